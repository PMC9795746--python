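"""Synthetic-data generators with planted ground truth for every pipeline stage.

Each generator takes a frozen spec (including a seed) and emits data of the
same shape the analysis modules consume from real experiments:

* Ig V-region nucleotide sequences with FR/CDR annotation and exact planted
  per-region hotspot-motif densities;
* Michaelis–Menten velocity datasets from v = Et*kcat*X/(Km+X) with
  multiplicative lognormal noise, with the substrate design in fmol
  converted to nM through the reaction volume;
* unimodal (Gaussian-in-temperature) activity profiles for optimum
  recovery;
* per-site ancestral-state posterior profiles with controlled ambiguity;
* serial-dilution detection series whose endpoint scales with a relative
  activity parameter.

All generators are deterministic for a fixed spec + seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .kinetics import DilutionSeries, KineticsDataset, ThermalProfile, fmol_to_nM
from .consensus import AncestralPosterior
from .motifs import AnnotatedIgV, MotifSet, builtin_motif_sets

__all__ = [
    "IgVSimSpec",
    "KineticsSimSpec",
    "ThermalSimSpec",
    "PosteriorSimSpec",
    "DilutionSimSpec",
    "DEFAULT_REGION_LENGTHS",
    "DEFAULT_SUBSTRATE_GRID_FMOL",
    "gen_igv_set",
    "gen_kinetics",
    "gen_thermal",
    "gen_posteriors",
    "gen_dilution_series",
    "gen_dilution_pair",
]

#: Typical IMGT-style nucleotide lengths of IgV heavy-chain subsegments.
DEFAULT_REGION_LENGTHS: dict[str, int] = {
    "FR1": 75,
    "CDR1": 24,
    "FR2": 51,
    "CDR2": 24,
    "FR3": 114,
}

#: Two-fold substrate dilution series, 0.0625-100 fmol.
DEFAULT_SUBSTRATE_GRID_FMOL: tuple[float, ...] = (
    0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 100.0,
)

_REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3")
_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class IgVSimSpec:
    """Ground-truth parameters for a synthetic annotated IgV sequence set."""

    n_sequences: int
    cdr_motif_density: float
    fr_motif_density: float
    gc_content: float = 0.5
    motif_set_id: str = "WRC_GYW"
    region_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REGION_LENGTHS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be positive")
        if self.cdr_motif_density < 0 or self.fr_motif_density < 0:
            raise ValueError("motif densities must be non-negative")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must lie in [0, 1]")
        if self.motif_set_id not in builtin_motif_sets():
            raise ValueError(f"unknown motif set {self.motif_set_id!r}")
        k = builtin_motif_sets()[self.motif_set_id].word_length
        for name, length in self.region_lengths.items():
            if name not in _REGION_ORDER:
                raise ValueError(f"unknown region name {name!r}")
            if length < k:
                raise ValueError(f"region {name} shorter than motif length {k}")


@dataclass(frozen=True)
class KineticsSimSpec:
    """Ground truth for a simulated deamination kinetics experiment."""

    kcat: float  # min^-1
    km: float  # nM
    et: float  # nM
    substrate_grid_fmol: tuple[float, ...] = DEFAULT_SUBSTRATE_GRID_FMOL
    reaction_volume_ul: float = 10.0
    noise_cv: float = 0.0
    replicates: int = 2
    seed: int = 0
    enzyme_id: str = "sim"

    def __post_init__(self) -> None:
        if min(self.kcat, self.km, self.et) <= 0:
            raise ValueError("kcat, km, et must be positive")
        if any(s <= 0 for s in self.substrate_grid_fmol):
            raise ValueError("substrate grid must be strictly positive")
        if self.reaction_volume_ul <= 0:
            raise ValueError("reaction volume must be positive")
        if self.noise_cv < 0 or self.replicates < 1:
            raise ValueError("invalid noise_cv or replicates")


@dataclass(frozen=True)
class ThermalSimSpec:
    """Ground truth for a unimodal activity-vs-temperature profile."""

    t_opt: float  # °C
    breadth: float = 8.0  # °C, sd of the Gaussian performance curve
    peak_activity: float = 50.0  # % deamination at the optimum
    grid: tuple[float, ...] = tuple(float(t) for t in range(-10, 41, 2))
    noise_cv: float = 0.0
    replicates: int = 2
    seed: int = 0
    enzyme_id: str = "sim"

    def __post_init__(self) -> None:
        if self.breadth <= 0:
            raise ValueError("breadth must be positive")
        if not 0 < self.peak_activity <= 100:
            raise ValueError("peak_activity must lie in (0, 100]")
        if self.noise_cv < 0 or self.replicates < 1:
            raise ValueError("invalid noise_cv or replicates")


@dataclass(frozen=True)
class PosteriorSimSpec:
    """Ground truth for per-site ancestral-state posterior profiles.

    ``ambiguous_sites`` maps a 1-based site to (alternative residue,
    probability mass on the alternative); the remaining mass stays on the
    true residue.
    """

    true_sequence: str
    methods: tuple[str, ...] = ("mrbayes", "raxml", "protasr")
    ambiguous_sites: Mapping[int, tuple[str, float]] = field(default_factory=dict)
    node_id: str = "ANC"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_sequence:
            raise ValueError("true_sequence must be non-empty")
        for site, (alt, p) in self.ambiguous_sites.items():
            if not 1 <= site <= len(self.true_sequence):
                raise ValueError(f"ambiguous site {site} outside 1..{len(self.true_sequence)}")
            if not 0 < p < 1:
                raise ValueError(f"alternative probability at site {site} must lie in (0, 1)")
            if alt == self.true_sequence[site - 1]:
                raise ValueError(f"site {site}: alternative equals the true residue")


@dataclass(frozen=True)
class DilutionSimSpec:
    """Ground truth for a serial-dilution PCR detection series.

    ``reference_endpoint`` anchors absolute detectability: an enzyme with
    relative_activity 1 is detected up to that dilution factor; an enzyme
    k-fold more active is detected up to k times deeper dilution.
    """

    relative_activity: float
    dilution_grid: tuple[float, ...] = (2.0, 1e1, 1e2, 1e3, 1e4, 1e5, 1e6)
    replicates: int = 4
    detection_noise: float = 0.0
    reference_endpoint: float = 1e4
    seed: int = 0
    enzyme_id: str = "sim"

    def __post_init__(self) -> None:
        if self.relative_activity <= 0:
            raise ValueError("relative_activity must be positive")
        if any(b <= a for a, b in zip(self.dilution_grid, self.dilution_grid[1:])):
            raise ValueError("dilution grid must be strictly increasing")
        if not 0 <= self.detection_noise < 0.5:
            raise ValueError("detection_noise must lie in [0, 0.5)")
        if self.replicates < 1 or self.reference_endpoint <= 0:
            raise ValueError("invalid replicates or reference_endpoint")


# ---------------------------------------------------------------------------
# IgV sequences with planted motif densities


def _sample_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(np.arange(4), size=n, p=probs)


def _place_starts(
    rng: np.random.Generator, length: int, count: int, word_len: int, gap: int = 1
) -> np.ndarray:
    """Uniformly sample ``count`` word start positions with a minimum gap.

    Uses the classic stars-and-bars reduction so that every admissible
    non-overlapping placement is equally likely.
    """
    if count == 0:
        return np.array([], dtype=int)
    stride = word_len + gap
    slots = length - word_len + 1 - (count - 1) * (stride - 1)
    if slots < count:
        raise ValueError(
            f"cannot place {count} motifs of length {word_len} (min gap {gap}) "
            f"in a region of {length} nt"
        )
    picks = np.sort(rng.choice(slots, size=count, replace=False))
    return picks + np.arange(count) * (stride - 1)


def _scrub_spontaneous(
    rng: np.random.Generator,
    seq: np.ndarray,
    words: set[str],
    word_len: int,
    planted_starts: set[int],
    planted_mask: np.ndarray,
    max_passes: int = 200,
) -> None:
    """Mutate background bases until no unplanted window matches a motif word."""
    base_index = {b: i for i, b in enumerate(_BASES)}
    for _ in range(max_passes):
        changed = False
        chars = "".join(_BASES[seq])
        for i in range(len(seq) - word_len + 1):
            if i in planted_starts or chars[i : i + word_len] not in words:
                continue
            editable = [j for j in range(i, i + word_len) if not planted_mask[j]]
            if not editable:  # cannot occur with gap >= 1 placement
                raise RuntimeError("unscrubbable spontaneous motif inside planted spans")
            j = int(rng.choice(editable))
            window = list(chars[i : i + word_len])
            pos = j - i
            breaking = [
                b for b in "ACGT"
                if b != window[pos] and "".join(window[:pos] + [b] + window[pos + 1 :]) not in words
            ]
            seq[j] = base_index[rng.choice(breaking)]
            changed = True
            chars = "".join(_BASES[seq])
        if not changed:
            return
    raise RuntimeError("motif scrubbing did not converge")


def gen_igv_set(spec: IgVSimSpec) -> list[AnnotatedIgV]:
    """Generate annotated IgV-like sequences with exact planted motif densities.

    Background bases are drawn at the requested GC content; spontaneous
    motif occurrences are removed by resampling background bases; then
    ``round(density * region_length)`` motif words are planted per region at
    uniformly random non-overlapping positions (minimum gap 1 nt, so no
    junction window can create an extra motif).  The realized per-region
    count therefore equals the planted count exactly.
    """
    rng = np.random.default_rng(spec.seed)
    motifs = builtin_motif_sets()[spec.motif_set_id]
    k = motifs.word_length
    words = set(motifs.words)
    region_items = [(r, spec.region_lengths[r]) for r in _REGION_ORDER if r in spec.region_lengths]
    total_len = sum(length for _, length in region_items)

    out = []
    for idx in range(spec.n_sequences):
        seq = _sample_background(rng, total_len, spec.gc_content)
        regions: dict[str, tuple[int, int]] = {}
        planted_starts: set[int] = set()
        planted_mask = np.zeros(total_len, dtype=bool)
        offset = 0
        for region, length in region_items:
            regions[region] = (offset, offset + length)
            density = spec.cdr_motif_density if region.startswith("CDR") else spec.fr_motif_density
            count = int(round(density * length))
            starts = _place_starts(rng, length, count, k) + offset
            for s in starts:
                word = motifs.words[rng.integers(len(motifs.words))]
                seq[s : s + k] = [list("ACGT").index(c) for c in word]
                planted_starts.add(int(s))
                planted_mask[s : s + k] = True
            offset += length
        _scrub_spontaneous(rng, seq, words, k, planted_starts, planted_mask)
        out.append(
            AnnotatedIgV(
                seq_id=f"igv_{idx:04d}",
                sequence="".join(_BASES[seq]),
                regions=regions,
                species_id="synthetic",
            )
        )
    return out


# ---------------------------------------------------------------------------
# kinetics / thermal / posterior / dilution generators


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def gen_kinetics(spec: KineticsSimSpec) -> KineticsDataset:
    """Simulate velocities from v = Et*kcat*X/(Km+X) with lognormal noise."""
    rng = np.random.default_rng(spec.seed)
    obs = []
    for rep in range(spec.replicates):
        for fmol in spec.substrate_grid_fmol:
            x = fmol_to_nM(fmol, spec.reaction_volume_ul)
            v = spec.et * spec.kcat * x / (spec.km + x)
            v *= float(_lognormal_factors(rng, spec.noise_cv, 1)[0])
            obs.append((x, v, rep))
    return KineticsDataset(enzyme_id=spec.enzyme_id, observations=obs, et=spec.et)


def gen_thermal(spec: ThermalSimSpec) -> ThermalProfile:
    """Simulate a Gaussian thermal performance curve with multiplicative noise."""
    if not min(spec.grid) <= spec.t_opt <= max(spec.grid):
        warnings.warn("temperature grid does not cover t_opt", stacklevel=2)
    rng = np.random.default_rng(spec.seed)
    points = []
    for rep in range(spec.replicates):
        for t in spec.grid:
            act = spec.peak_activity * np.exp(-((t - spec.t_opt) ** 2) / (2 * spec.breadth**2))
            act *= float(_lognormal_factors(rng, spec.noise_cv, 1)[0])
            points.append((float(t), float(np.clip(act, 0.0, 100.0)), rep))
    return ThermalProfile(enzyme_id=spec.enzyme_id, points=points)


def gen_posteriors(spec: PosteriorSimSpec) -> list[AncestralPosterior]:
    """One posterior profile per method: certainty 1.0 except at planted splits."""
    profiles = []
    for method in spec.methods:
        profile: list[dict[str, float]] = []
        for i, residue in enumerate(spec.true_sequence):
            site = i + 1
            if site in spec.ambiguous_sites:
                alt, p = spec.ambiguous_sites[site]
                profile.append({residue: 1.0 - p, alt: p})
            else:
                profile.append({residue: 1.0})
        profiles.append(AncestralPosterior(method=method, node_id=spec.node_id, profile=profile))
    return profiles


def gen_dilution_series(spec: DilutionSimSpec) -> DilutionSeries:
    """Simulate detection outcomes: positive while dilution <= scaled endpoint.

    The true endpoint is reference_endpoint * relative_activity; each
    replicate call is flipped with probability detection_noise.
    """
    rng = np.random.default_rng(spec.seed)
    endpoint = spec.reference_endpoint * spec.relative_activity
    detections = []
    for _ in range(spec.replicates):
        row = []
        for d in spec.dilution_grid:
            detected = d <= endpoint
            if spec.detection_noise > 0 and rng.random() < spec.detection_noise:
                detected = not detected
            row.append(bool(detected))
        detections.append(row)
    return DilutionSeries(
        enzyme_id=spec.enzyme_id, grid=list(spec.dilution_grid), detections=detections
    )


def gen_dilution_pair(
    spec_a: DilutionSimSpec, spec_b: DilutionSimSpec
) -> tuple[DilutionSeries, DilutionSeries]:
    """Two detection series on a shared grid, for fold-difference estimation."""
    if spec_a.dilution_grid != spec_b.dilution_grid:
        raise ValueError("dilution specs must share a grid")
    return gen_dilution_series(spec_a), gen_dilution_series(spec_b)
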