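"""Peptide-to-protein filtering, per-run standardization, and scalar ETC scores.

Label-free proteomic quantitation is taken from peptide level to a
samples x proteins abundance matrix with the filters used for the tumor
cohort: a peptide contributes only if its signal strictly exceeds 10,000 in
at least 5% of samples, a protein is reported only if at least 2 retained
unique peptides support it, and abundances (sum of retained peptide
signals, log-transformed) are z-scored per acquisition run.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the five ETC subunits quantified by western blot (one per respiratory complex)
WB_PANEL = ["ATP5A", "UQCR2", "SDHB", "COXII", "NDUFB8"]


@dataclass
class ProteinMatrix:
    """Samples x proteins abundance grid with per-sample run labels.

    ``values`` is a float DataFrame (index = sample ids, columns = protein
    ids) with NaN marking missing quantifications; ``runs`` maps each sample
    to its acquisition run.
    """

    values: pd.DataFrame
    runs: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        self.runs = self.runs.reindex(self.values.index)
        if self.runs.isna().any():
            missing = self.runs.index[self.runs.isna()].tolist()
            raise ValueError(f"samples without a run label: {missing}")
        self.values = self.values.astype(float)
        self.values.index.name = "sample_id"

    @property
    def samples(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def proteins(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()


@dataclass
class PeptideTable:
    """Peptide-level quantitation: one row per peptide, one signal per sample."""

    peptide: pd.Series  # peptide id per row
    protein: pd.Series  # parent protein id per row
    unique: pd.Series  # bool: peptide maps to a single protein
    signals: pd.DataFrame  # rows align with peptides; columns = sample ids
    runs: pd.Series = field(default=None)  # run label per sample (optional)

    def __post_init__(self) -> None:
        n = len(self.peptide)
        if not (len(self.protein) == len(self.unique) == len(self.signals) == n):
            raise ValueError("peptide table fields must have equal length")
        if (self.signals.to_numpy() < 0).any():
            raise ValueError("peptide signals must be non-negative")
        if self.runs is None:
            self.runs = pd.Series("run1", index=self.signals.columns)


def filter_peptides(
    pep: PeptideTable,
    signal_floor: float = 10_000,
    prevalence: float = 0.05,
    min_unique: int = 2,
    log_transform: bool = True,
) -> tuple[set[str], ProteinMatrix]:
    """Apply the peptide and protein identification filters.

    A peptide is retained iff its signal strictly exceeds ``signal_floor``
    in at least ``ceil(prevalence * n_samples)`` samples.  A protein is
    retained iff at least ``min_unique`` retained *unique* peptides map to
    it.  Protein abundance is the per-sample sum of its retained peptides'
    signals (unique and non-conflicting alike are summed once a protein is
    identified), log-transformed by default; samples where no retained
    peptide has signal are left missing.
    """
    if not (0 < prevalence <= 1):
        raise ValueError("prevalence must be in (0, 1]")
    if signal_floor < 0:
        raise ValueError("signal_floor must be non-negative")
    n_samples = pep.signals.shape[1]
    if len(pep.peptide) == 0 or n_samples == 0:
        empty = pd.DataFrame(index=pep.signals.columns)
        return set(), ProteinMatrix(empty, pep.runs)

    required = math.ceil(prevalence * n_samples)
    above = (pep.signals > signal_floor).sum(axis=1)
    retained = above.to_numpy() >= required

    unique_retained = retained & pep.unique.to_numpy(dtype=bool)
    support = pd.Series(pep.protein.to_numpy()[unique_retained]).value_counts()
    kept_proteins = set(support.index[support >= min_unique])

    cols: dict[str, pd.Series] = {}
    for prot in sorted(kept_proteins):
        rows = retained & (pep.protein.to_numpy() == prot)
        abundance = pep.signals.loc[rows].sum(axis=0)
        if log_transform:
            with np.errstate(divide="ignore"):
                abundance = np.log(abundance.where(abundance > 0))
        cols[prot] = abundance
    values = pd.DataFrame(cols, index=pep.signals.columns)
    return kept_proteins, ProteinMatrix(values, pep.runs)


def standardize_per_run(m: ProteinMatrix) -> ProteinMatrix:
    """Center and scale each protein to unit sample s.d. within each run.

    Missing entries stay missing; a protein with zero variance within a run
    is set to all-zero there (with a logged warning) rather than erroring.
    """
    out = m.values.copy()
    for run, sample_idx in m.runs.groupby(m.runs).groups.items():
        block = out.loc[sample_idx]
        mean = block.mean(axis=0, skipna=True)
        sd = block.std(axis=0, ddof=1, skipna=True)
        degenerate = (sd == 0) | sd.isna()
        if degenerate.any():
            bad = [p for p, d in zip(block.columns, degenerate) if d and block[p].notna().any()]
            if bad:
                logger.warning(
                    "run %s: zero-variance proteins set to 0: %s", run, bad
                )
        sd = sd.replace(0, np.nan)
        z = (block - mean) / sd
        z = z.where(~block.isna(), np.nan)
        z = z.fillna(0.0).where(~block.isna(), np.nan)
        out.loc[sample_idx] = z
    return ProteinMatrix(out, m.runs.copy())


def mean_panel_score(m: ProteinMatrix, panel: list[str]) -> pd.Series:
    """Per-sample arithmetic mean over the non-missing panel proteins."""
    present = [p for p in panel if p in m.values.columns]
    if not present:
        raise ValueError(f"no panel protein present in matrix (panel: {panel})")
    return m.values[present].mean(axis=1, skipna=True)


def wb_etc_score(bands: pd.DataFrame, actin: pd.Series) -> pd.Series:
    """Mean of the five western-blot ETC band intensities normalized to actin.

    ``bands`` has one column per ETC protein and one row per sample; the
    score for a sample is mean_p(band_p / actin).
    """
    actin = actin.reindex(bands.index)
    if (actin <= 0).any() or actin.isna().any():
        raise ValueError("actin intensity must be positive for every sample")
    return bands.div(actin, axis=0).mean(axis=1)


def carbonylation_score(carbonylated_signal: float, total_signal: float) -> float:
    """Protein-oxidation readout: carbonylated signal / total protein signal."""
    if total_signal <= 0:
        raise ValueError("total protein signal must be positive")
    if carbonylated_signal < 0:
        raise ValueError("carbonylated signal must be non-negative")
    return carbonylated_signal / total_signal
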