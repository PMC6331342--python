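"""Synthetic cohort generators with recorded ground truth.

Each generator emulates one input of the tumor-stratification pipeline —
a two-subgroup proteomic cohort with run batch effects and missingness,
allele-specific copy-number profiles with a constructed number of
LST-qualifying breakpoints plus sub-3-Mb variant noise, survival data with
a subgroup hazard ratio, fluorescence fields with known cell and focus
counts, and exponential xenograft growth series with a treatment effect —
and returns the truth alongside, so recovery can be asserted exactly.

Defaults mirror the cohort the pipeline was designed around: 127 tumors
(53 low-, 74 high-OXPHOS) quantified over two acquisition runs with a
27-protein ETC panel among 360 metabolic proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .lst import MB, CopyNumberProfile, SegmentRecord, ploidy_class
from .prep import ProteinMatrix

#: synthetic ETC panel ids (27 proteins, as in the proteomic panel)
ETC_PANEL = [f"ETC{i:02d}" for i in range(1, 28)]

#: chromosome lengths (bp) of a human-scale autosome set, rounded to Mb
DEFAULT_CHROM_LENGTHS = [
    int(l * MB)
    for l in (249, 242, 198, 190, 182, 171, 159, 145, 138, 134,
              135, 133, 114, 107, 102, 90, 83, 80, 59, 64, 47, 51)
]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# proteomic cohort


@dataclass(frozen=True)
class CohortTruth:
    subgroup: pd.Series  # per-sample {"low", "high"}
    delta: float  # ETC shift in s.d. units
    run: pd.Series  # per-sample acquisition run
    missing_rate: float


def gen_proteomics(
    n_low: int = 53,
    n_high: int = 74,
    n_etc: int = 27,
    n_other: int = 333,
    delta: float = 2.0,
    n_runs: int = 2,
    missing_rate: float = 0.05,
    run_effect_sd: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> tuple[ProteinMatrix, CohortTruth]:
    """Two-subgroup log-abundance matrix with run effects and missingness.

    Log abundance of protein p in sample s is
    ``mu_p + delta * 1[s high] * 1[p ETC] + beta_run(s) + eps`` with
    ``eps ~ N(0, 1)``; protein baselines and run effects are drawn once per
    generation.  Entries are masked missing uniformly at random.
    """
    if min(n_low, n_high, n_etc, n_runs) < 1 or n_other < 0:
        raise ValueError("counts must be at least 1 (n_other may be 0)")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = _rng(seed)

    n = n_low + n_high
    samples = [f"S{i:03d}" for i in range(1, n + 1)]
    groups = np.array(["low"] * n_low + ["high"] * n_high)
    rng.shuffle(groups)
    etc = [f"ETC{i:02d}" for i in range(1, n_etc + 1)]
    other = [f"OTH{i:03d}" for i in range(1, n_other + 1)]
    proteins = etc + other

    mu = rng.normal(0.0, 1.0, size=len(proteins))
    beta = rng.normal(0.0, run_effect_sd, size=n_runs)
    run_of = rng.integers(n_runs, size=n)

    x = mu[None, :] + rng.normal(0.0, 1.0, size=(n, len(proteins)))
    x[:, :n_etc] += delta * (groups == "high")[:, None]
    x += beta[run_of][:, None]
    if missing_rate > 0:
        x = np.where(rng.random(x.shape) < missing_rate, np.nan, x)

    values = pd.DataFrame(x, index=samples, columns=proteins)
    runs = pd.Series([f"run{r + 1}" for r in run_of], index=samples, name="run")
    truth = CohortTruth(
        subgroup=pd.Series(groups, index=samples, name="subgroup"),
        delta=delta,
        run=runs.copy(),
        missing_rate=missing_rate,
    )
    return ProteinMatrix(values, runs), truth


# ---------------------------------------------------------------------------
# copy-number scars


@dataclass(frozen=True)
class ScarTruth:
    true_lst_count: int
    ploidy_class: str
    small_cnv_count: int


def _split_lengths(
    total: int, n_parts: int, min_len: int, rng: np.random.Generator
) -> list[int]:
    """Random partition of ``total`` into ``n_parts`` parts, each >= min_len."""
    slack = total - n_parts * min_len
    cuts = np.sort(rng.integers(0, slack + 1, size=n_parts - 1)) if n_parts > 1 else np.array([], dtype=int)
    pieces = np.diff(np.concatenate([[0], cuts, [slack]]))
    return [min_len + int(p) for p in pieces]


def gen_cn_profile(
    chrom_lengths: list[int] | None = None,
    base_total_cn: int = 2,
    n_lst_true: int = 0,
    n_small_cnv: int = 0,
    min_region_mb: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> tuple[CopyNumberProfile, ScarTruth]:
    """Profile with exactly ``n_lst_true`` qualifying breakpoints.

    Breakpoints alternate between two states differing in both total and
    major copy number, with every inter-breakpoint segment at least 10 Mb,
    so each placed breakpoint qualifies as an LST by construction.  Small
    variant segments (< 3 Mb, one per host segment, inset at least 3 Mb from
    the host ends) are inserted strictly inside large segments; smoothing
    removes them and restores the host exactly, so the constructed count is
    the ground truth.
    """
    if chrom_lengths is None:
        chrom_lengths = DEFAULT_CHROM_LENGTHS
    rng = _rng(seed)
    min_seg = int(round(min_region_mb * MB))
    if n_lst_true > 0 and any(l < 2 * min_seg + 5 * MB for l in chrom_lengths):
        raise ValueError("every chromosome must be >= 25 Mb when placing LST")

    b = base_total_cn
    state_a = (b, math.ceil(b / 2))
    state_b = (b + 1, math.ceil((b + 1) / 2))

    # allocate breakpoints to chromosomes within capacity
    caps = [l // min_seg - 1 for l in chrom_lengths]
    if n_lst_true > sum(max(c, 0) for c in caps):
        raise ValueError(
            f"cannot place {n_lst_true} LST: genome capacity is {sum(max(c, 0) for c in caps)}"
        )
    alloc = [0] * len(chrom_lengths)
    open_idx = [i for i, c in enumerate(caps) if c > 0]
    for _ in range(n_lst_true):
        i = int(rng.choice(open_idx))
        alloc[i] += 1
        if alloc[i] >= caps[i]:
            open_idx.remove(i)
            if not open_idx and sum(alloc) < n_lst_true:
                raise ValueError("infeasible LST placement")

    segments: dict[str, list[SegmentRecord]] = {}
    hosts: list[tuple[str, int]] = []  # (chrom, segment index) able to host a CNV
    for ci, (length, nb) in enumerate(zip(chrom_lengths, alloc)):
        chrom = f"chr{ci + 1}"
        lengths = _split_lengths(length, nb + 1, min_seg, rng)
        segs, pos = [], 0
        for si, seg_len in enumerate(lengths):
            state = state_a if si % 2 == 0 else state_b
            segs.append(SegmentRecord(chrom, pos, pos + seg_len, *state))
            pos += seg_len
        segments[chrom] = segs
        hosts.extend((chrom, si) for si, s in enumerate(segs) if s.length >= 10 * MB)

    if n_small_cnv > len(hosts):
        raise ValueError(
            f"cannot place {n_small_cnv} small CNVs in {len(hosts)} host segments"
        )
    chosen = rng.choice(len(hosts), size=n_small_cnv, replace=False) if n_small_cnv else []
    # insert from the right so earlier indices stay valid
    for hi in sorted((int(i) for i in chosen), key=lambda i: (hosts[i][0], -hosts[i][1])):
        chrom, si = hosts[hi]
        host = segments[chrom][si]
        cnv_len = int(rng.integers(int(0.5 * MB), int(2.9 * MB)))
        lo = host.start + 3 * MB
        hi_bound = host.end - 3 * MB - cnv_len
        start = int(rng.integers(lo, hi_bound + 1))
        cnv_state = (host.total_cn + 2, host.major_cn + 2)
        segments[chrom][si : si + 1] = [
            SegmentRecord(chrom, host.start, start, *host.state),
            SegmentRecord(chrom, start, start + cnv_len, *cnv_state),
            SegmentRecord(chrom, start + cnv_len, host.end, *host.state),
        ]

    profile = CopyNumberProfile(segments)
    from .lst import dna_index  # local import to avoid cycle at module load

    truth = ScarTruth(
        true_lst_count=n_lst_true,
        ploidy_class=ploidy_class(dna_index(profile)),
        small_cnv_count=int(n_small_cnv),
    )
    return profile, truth


# ---------------------------------------------------------------------------
# survival


def _censor_horizon(rate_param: float, censor_rate: float) -> float:
    """Uniform-censoring horizon T with P(censored) == censor_rate.

    For X ~ Exp(lam) and C ~ U(0, T), P(C < X) = (1 - exp(-lam*T)) / (lam*T);
    solve for T.
    """
    if censor_rate <= 0:
        return math.inf
    f = lambda u: (1 - math.exp(-u)) / u - censor_rate
    u = brentq(f, 1e-9, 1e9)
    return u / rate_param


def gen_survival(
    n_per_group: int = 50,
    hazard_ratio: float = 2.0,
    baseline_median: float = 60.0,
    censor_rate: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Two-group exponential survival data with uniform censoring.

    The ``high`` group has the baseline hazard (median ``baseline_median``
    months); the ``low`` group's hazard is multiplied by ``hazard_ratio``.
    A continuous ``score`` (higher in the high group) is attached so the
    table can drive cutoff stratification.  Columns: time (months), event
    (1 = death observed), group, score.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    rng = _rng(seed)
    lam0 = math.log(2) / baseline_median
    rows = []
    for group, lam, score_mu in (("high", lam0, 1.0), ("low", lam0 * hazard_ratio, -1.0)):
        x = rng.exponential(1 / lam, size=n_per_group)
        horizon = _censor_horizon(lam, censor_rate)
        c = rng.uniform(0, horizon, size=n_per_group) if math.isfinite(horizon) else np.full(n_per_group, math.inf)
        time = np.minimum(x, c)
        event = (x <= c).astype(int)
        score = rng.normal(score_mu, 1.0, size=n_per_group)
        for t, e, s in zip(time, event, score):
            rows.append({"time": float(t), "event": int(e), "group": group, "score": float(s)})
    table = pd.DataFrame(rows)
    table.index = [f"P{i:03d}" for i in range(1, len(table) + 1)]
    return table


# ---------------------------------------------------------------------------
# foci imagery


@dataclass(frozen=True)
class FociField:
    """Two-channel synthetic fluorescence field.

    ``nuclei`` carries the cell discs (for cell counting at threshold
    0.180); ``foci`` carries the nuclear bodies (for focus counting at
    threshold 0.150) over a faint diffuse nuclear background.
    """

    nuclei: np.ndarray
    foci: np.ndarray
    cell_centers: list[tuple[float, float, float]]  # (row, col, radius)
    focus_centers: list[tuple[float, float, float]]

    @property
    def n_cells(self) -> int:
        return len(self.cell_centers)

    @property
    def n_foci(self) -> int:
        return len(self.focus_centers)


def _paint_disc(img: np.ndarray, r: float, c: float, radius: float, level: float) -> None:
    rr, cc = np.ogrid[: img.shape[0], : img.shape[1]]
    mask = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
    img[mask] = np.maximum(img[mask], level)


def gen_foci_image(
    width: int = 256,
    height: int = 256,
    n_cells: int = 5,
    cell_radius: float = 12.0,
    foci_per_cell: int = 3,
    focus_radius: float = 2.0,
    cell_level: float = 0.5,
    focus_level: float = 0.9,
    nuclear_background: float = 0.05,
    noise_sd: float = 0.01,
    seed: int | np.random.Generator = 0,
    max_tries: int = 10_000,
) -> FociField:
    """Non-overlapping cell discs with foci inside, plus Gaussian noise.

    Discs are placed by rejection sampling; foci sit strictly inside their
    cell and do not touch each other.  Both channels are clipped to [0, 1].
    """
    if not (0 < cell_level <= 1 and 0 < focus_level <= 1):
        raise ValueError("disc levels must be in (0, 1]")
    rng = _rng(seed)
    nuclei = np.zeros((height, width))
    foci = np.zeros((height, width))

    cells: list[tuple[float, float, float]] = []
    tries = 0
    margin = cell_radius + 2
    while len(cells) < n_cells:
        tries += 1
        if tries > max_tries:
            raise ValueError("cannot place non-overlapping cells; reduce n_cells or radius")
        r = rng.uniform(margin, height - margin)
        c = rng.uniform(margin, width - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 > (2 * cell_radius + 2) ** 2 for r0, c0, _ in cells):
            cells.append((r, c, cell_radius))
            _paint_disc(nuclei, r, c, cell_radius, cell_level)
            _paint_disc(foci, r, c, cell_radius, nuclear_background)

    foci_pts: list[tuple[float, float, float]] = []
    for r0, c0, _ in cells:
        placed = 0
        tries = 0
        while placed < foci_per_cell:
            tries += 1
            if tries > max_tries:
                raise ValueError("cannot place non-overlapping foci; reduce foci_per_cell")
            rho = rng.uniform(0, cell_radius - focus_radius - 1)
            theta = rng.uniform(0, 2 * np.pi)
            fr, fc = r0 + rho * np.sin(theta), c0 + rho * np.cos(theta)
            if all(
                (fr - r1) ** 2 + (fc - c1) ** 2 > (2 * focus_radius + 2) ** 2
                for r1, c1, _ in foci_pts
            ):
                foci_pts.append((fr, fc, focus_radius))
                _paint_disc(foci, fr, fc, focus_radius, focus_level)
                placed += 1

    if noise_sd > 0:
        nuclei = nuclei + rng.normal(0, noise_sd, nuclei.shape)
        foci = foci + rng.normal(0, noise_sd, foci.shape)
    return FociField(
        nuclei=np.clip(nuclei, 0, 1),
        foci=np.clip(foci, 0, 1),
        cell_centers=cells,
        focus_centers=foci_pts,
    )


# ---------------------------------------------------------------------------
# xenograft growth


def gen_growth(
    n_mice: int = 8,
    v0: float = 100.0,
    growth_rate: float = 0.1,
    treatment_effect: float = 0.15,
    days: list[int] | None = None,
    noise_cv: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Exponential tumor-volume series for a control and a treated arm.

    V(t) = v0 * exp((growth_rate - effect * treated) * t) * lognormal noise,
    with mean-one multiplicative noise of coefficient of variation
    ``noise_cv``.  Columns: mouse, arm, day, volume_mm3.
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    if days is None:
        days = [0, 3, 7, 10, 14, 17, 21]
    rng = _rng(seed)
    sigma = math.sqrt(math.log(1 + noise_cv**2)) if noise_cv > 0 else 0.0
    rows = []
    for arm, rate in (("control", growth_rate), ("treated", growth_rate - treatment_effect)):
        for m in range(n_mice):
            mouse = f"{arm[0]}{m + 1:02d}"
            for d in days:
                noise = math.exp(rng.normal(-sigma**2 / 2, sigma)) if sigma > 0 else 1.0
                rows.append(
                    {
                        "mouse": mouse,
                        "arm": arm,
                        "day": int(d),
                        "volume_mm3": v0 * math.exp(rate * d) * noise,
                    }
                )
    return pd.DataFrame(rows)
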