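"""Run configuration and seed management.

One ``RunConfig`` carries every tunable parameter of the pipeline with the
printed defaults of the source protocol (consensus: 1000 iterations, 80%
resampling; LST: 10 Mb flanks, 3 Mb filter, cutoffs 15/20, DNA index 1.3;
imaging: thresholds 0.180/0.150 with their size and circularity rules;
survival: 10% group-size floor).  A single integer seed drives all
stochastic steps through a spawned ``numpy`` generator hierarchy, so runs
are reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ConsensusConfig:
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    iterations: int = 1000
    resample_fraction: float = 0.8
    delta_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.resample_fraction <= 1):
            raise ValueError("resample_fraction must be in (0, 1]")
        if any(k < 2 or k > 10 for k in self.k_range):
            raise ValueError("k_range must lie within {2, ..., 10}")


@dataclass(frozen=True)
class LstConfig:
    min_region_mb: float = 10.0
    filter_mb: float = 3.0
    cutoff_near_diploid: int = 15
    cutoff_near_tetraploid: int = 20
    ploidy_threshold: float = 1.3

    def __post_init__(self) -> None:
        if min(self.min_region_mb, self.filter_mb, self.ploidy_threshold) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class ImagingConfig:
    cell_threshold: float = 0.180
    cell_min_area: int = 80
    cell_min_circularity: float = 0.4
    nb_threshold: float = 0.150
    nb_area_range: tuple[int, int] = (1, 25)
    nb_min_circularity: float = 0.6

    def __post_init__(self) -> None:
        if self.cell_threshold <= 0 or self.nb_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class SurvivalConfig:
    min_group_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.min_group_fraction < 0.5 or self.min_group_fraction == 0.5):
            raise ValueError("min_group_fraction must be in (0, 0.5]")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    lst: LstConfig = field(default_factory=LstConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)

    def spawn(self, n: int) -> list[np.random.Generator]:
        """Independent child generators derived from the single global seed."""
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)
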