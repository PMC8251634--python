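"""Synthetic comet-assay intensity profiles and %DNA-in-Tail scoring.

Each cell is represented by a 1-D fluorescence profile along the
electrophoresis axis — the marginal that fully determines %DNA in Tail —
laid out on a microwell grid as in a high-throughput comet chip. The
head is a truncated Gaussian; the migrated tail is an exponential decay
starting at the head/tail boundary, carrying the programmed fraction of
the cell's DNA. Scoring integrates intensity beyond the boundary and
reports it as a percentage of total intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Head truncation radius and default boundary placement, in head widths.
HEAD_SUPPORT_K = 3.0


@dataclass(frozen=True)
class CometProfile:
    """1-D intensity profile of one comet."""

    intensity: np.ndarray
    head_center: int
    pixel_scale: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if (arr < 0).any() or not np.isfinite(arr).all():
            raise ValueError("intensities must be finite and non-negative")
        object.__setattr__(self, "intensity", arr)


@dataclass
class CometSimConfig:
    """Synthetic comet study design.

    ``programmed_tail_fractions`` maps concentration to the expected
    fraction of DNA in the tail; defaults emulate a strongly
    concentration-responsive alkylating exposure. 300 cells per culture
    matches common scoring practice for chip-format comet assays.
    """

    cells_per_culture: int = 300
    profile_length: int = 256
    head_center: int = 48
    head_width: float = 6.0
    tail_decay_length: float = 40.0
    programmed_tail_fractions: dict[float, float] = field(
        default_factory=lambda: {
            0.0: 0.038, 6.25: 0.102, 25.0: 0.287, 50.0: 0.585, 100.0: 0.833,
        })
    cell_sd: float = 0.06
    noise_sd: float = 0.02  # relative (gain) noise per pixel
    microwells_per_row: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_culture < 1:
            raise ValueError("cells_per_culture must be >= 1")
        for f in self.programmed_tail_fractions.values():
            if not (0.0 <= f <= 1.0):
                raise ValueError("programmed tail fractions must lie in [0, 1]")


@dataclass(frozen=True)
class CometCell:
    concentration: float
    replicate: int
    microwell: tuple[int, int]
    profile: CometProfile
    true_tail_fraction: float


def _head_shape(length: int, center: int, width: float) -> np.ndarray:
    x = np.arange(length, dtype=float)
    shape = np.exp(-0.5 * ((x - center) / width) ** 2)
    shape[np.abs(x - center) > HEAD_SUPPORT_K * width] = 0.0
    return shape / shape.sum()


def _tail_shape(length: int, boundary: int, decay: float) -> np.ndarray:
    x = np.arange(length, dtype=float)
    shape = np.where(x > boundary, np.exp(-(x - boundary) / decay), 0.0)
    total = shape.sum()
    if total == 0:
        raise ValueError("tail support empty; enlarge profile_length")
    return shape / total


def _cell_fractions(
    rng: np.random.Generator, mean: float, sd: float, n: int,
) -> np.ndarray:
    """Per-cell tail fractions: Beta-distributed with the programmed
    mean (exactly, so cell-to-cell spread never biases the culture mean)
    and standard deviation ``sd`` where feasible on [0, 1]."""
    if sd <= 0 or mean <= 0.0 or mean >= 1.0:
        return np.full(n, mean)
    var = min(sd**2, 0.9 * mean * (1 - mean))
    kappa = mean * (1 - mean) / var - 1
    return rng.beta(mean * kappa, (1 - mean) * kappa, size=n)


def simulate_comets(
    config: CometSimConfig,
    replicates: int = 4,
    rng: np.random.Generator | None = None,
) -> list[CometCell]:
    """Simulate per-cell comet profiles for every concentration and
    replicate culture; records the per-cell true tail fraction."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    boundary = int(round(
        config.head_center + HEAD_SUPPORT_K * config.head_width))
    head = _head_shape(config.profile_length, config.head_center,
                       config.head_width)
    tail = _tail_shape(config.profile_length, boundary,
                       config.tail_decay_length)
    cells = []
    for conc, f_prog in sorted(config.programmed_tail_fractions.items()):
        for rep in range(1, replicates + 1):
            f_cell = _cell_fractions(rng, f_prog, config.cell_sd,
                                     config.cells_per_culture)
            for i, f in enumerate(f_cell):
                profile = (1 - f) * head + f * tail
                if config.noise_sd > 0:
                    # per-pixel gain noise: leaves empty regions empty and
                    # the intensity-ratio score unbiased
                    gain = np.clip(
                        rng.normal(1.0, config.noise_sd,
                                   config.profile_length), 0, None)
                    profile = profile * gain
                cells.append(CometCell(
                    concentration=float(conc),
                    replicate=rep,
                    microwell=(i // config.microwells_per_row,
                               i % config.microwells_per_row),
                    profile=CometProfile(profile, config.head_center),
                    true_tail_fraction=float(f),
                ))
    return cells


def score_percent_tail(
    profile: CometProfile,
    head_width: float = 6.0,
    boundary_k: float = HEAD_SUPPORT_K,
) -> float:
    """%DNA in Tail: intensity beyond the head/tail boundary as a
    percentage of total intensity.

    The boundary sits at head_center + ``boundary_k`` head widths; with
    the default it coincides with the edge of the head support, so an
    undamaged noiseless cell scores exactly 0. Scale-invariant and
    bounded in [0, 100] by construction.
    """
    total = float(profile.intensity.sum())
    if total <= 0:
        raise ValueError("zero total intensity; score undefined")
    boundary = profile.head_center + boundary_k * head_width
    idx = np.arange(len(profile.intensity))
    tail = float(profile.intensity[idx > boundary].sum())
    return 100.0 * tail / total


@dataclass(frozen=True)
class CultureSummary:
    concentration: float
    replicate: int
    n_cells: int
    mean_percent_tail: float
    median_percent_tail: float
    sd_percent_tail: float


def aggregate_culture(
    scores: Sequence[float],
    concentration: float = float("nan"),
    replicate: int = 0,
    n_min: int = 300,
) -> CultureSummary:
    """Summarize per-cell scores for one culture; warns (does not fail)
    when fewer than ``n_min`` cells were scored."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("no scores to aggregate")
    if arr.size < n_min:
        warnings.warn(
            f"only {arr.size} cells scored (< {n_min})", stacklevel=2)
    return CultureSummary(
        concentration=concentration,
        replicate=replicate,
        n_cells=int(arr.size),
        mean_percent_tail=float(arr.mean()),
        median_percent_tail=float(np.median(arr)),
        sd_percent_tail=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    )


def score_study(
    cells: Sequence[CometCell],
    head_width: float = 6.0,
    n_min: int = 300,
) -> list[CultureSummary]:
    """Score every cell and aggregate per culture (concentration x
    replicate), ready for the dose-response layer."""
    by_culture: dict[tuple[float, int], list[float]] = {}
    for cell in cells:
        by_culture.setdefault(
            (cell.concentration, cell.replicate), []).append(
            score_percent_tail(cell.profile, head_width=head_width))
    return [
        aggregate_culture(scores, concentration=conc, replicate=rep,
                          n_min=n_min)
        for (conc, rep), scores in sorted(by_culture.items())
    ]
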