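"""Fragmentation-landscape statistics.

Charge normalization, per-site abundance profiles, sequence coverage,
sequence tags, residue-pair cleavage heat maps, transmembrane-topology
enrichment, and IRMPD-vs-HCD modality comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .fragment_match import FragmentMatch
from .masses_ions import ProteinSpec

__all__ = [
    "AMINO_ACIDS",
    "SiteProfile",
    "SequenceTag",
    "TopologyEnrichment",
    "normalize_by_charge",
    "site_profile",
    "coverage",
    "sequence_tags",
    "pair_heatmap",
    "topology_enrichment",
    "compare_modalities",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

NormalizationMode = Literal["divide", "multiply", "none"]


def normalize_by_charge(
    matches: list[FragmentMatch], mode: NormalizationMode = "divide"
) -> list[FragmentMatch]:
    """Fill ``normalized_intensity`` from raw intensity and charge (in place).

    The default divides by z (image-current response scales with charge, so
    dividing estimates ion counts); ``multiply`` and ``none`` are provided
    for instruments with other response models.
    """
    for m in matches:
        if mode == "divide":
            m.normalized_intensity = m.raw_intensity / m.z
        elif mode == "multiply":
            m.normalized_intensity = m.raw_intensity * m.z
        elif mode == "none":
            m.normalized_intensity = m.raw_intensity
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
    return matches


def _require_normalized(matches: list[FragmentMatch]) -> None:
    for m in matches:
        if m.normalized_intensity is None:
            raise ValueError("call normalize_by_charge before landscape statistics")


@dataclass
class SiteProfile:
    """Per-cleavage-site summary of matched fragment evidence.

    ``abundance`` is the summed charge-normalized intensity rescaled so the
    maximum site equals 100; ``raw_abundance`` keeps the pre-rescale sums
    (used for conservation checks against the pair heat map).
    """

    L: int
    abundance: np.ndarray          # length L-1, max = 100 when any match exists
    raw_abundance: np.ndarray      # pre-rescale sums
    weighted_avg_charge: np.ndarray
    n_charge_states: np.ndarray
    ion_types: list[set[str]]

    @property
    def sites(self) -> np.ndarray:
        return np.arange(1, self.L)


def site_profile(matches: list[FragmentMatch], L: int) -> SiteProfile:
    """Sum charge-normalized intensities per site; rescale max site to 100."""
    if L < 2:
        raise ValueError("sequence length must be >= 2")
    _require_normalized(matches)
    raw = np.zeros(L - 1)
    zsum = np.zeros(L - 1)
    zstates: list[set[int]] = [set() for _ in range(L - 1)]
    itypes: list[set[str]] = [set() for _ in range(L - 1)]
    for m in matches:
        i = m.site - 1
        raw[i] += m.normalized_intensity
        zsum[i] += m.z * m.normalized_intensity
        zstates[i].add(m.z)
        itypes[i].add(m.ion_type)
    with np.errstate(invalid="ignore", divide="ignore"):
        wavg = np.where(raw > 0, zsum / np.where(raw > 0, raw, 1.0), 0.0)
    peak = raw.max()
    abundance = raw * (100.0 / peak) if peak > 0 else raw.copy()
    return SiteProfile(
        L=L,
        abundance=abundance,
        raw_abundance=raw,
        weighted_avg_charge=wavg,
        n_charge_states=np.array([len(s) for s in zstates]),
        ion_types=itypes,
    )


def coverage(matches: list[FragmentMatch], L: int) -> float:
    """Sequence coverage in percent: distinct matched sites over L−1 sites."""
    if L < 2:
        raise ValueError("sequence length must be >= 2")
    return 100.0 * len({m.site for m in matches}) / (L - 1)


@dataclass(frozen=True)
class SequenceTag:
    """A residue stretch delimited on both sides by observed cleavages."""

    start: int           # first residue of the tag (1-based)
    end: int             # last residue of the tag (inclusive)
    residues: str
    sites: tuple[int, ...]  # consecutive supporting cleavage sites

    def __len__(self) -> int:
        return len(self.residues)


def sequence_tags(
    matches: list[FragmentMatch], sequence: str, min_len: int = 3
) -> list[SequenceTag]:
    """Extract maximal runs of consecutive matched sites as sequence tags.

    A run of sites ``i..i+k`` delimits residues ``i+1..i+k`` (every residue
    in the tag is flanked by observed cleavages); only tags of length
    ``>= min_len`` are returned.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    sites = sorted({m.site for m in matches})
    tags: list[SequenceTag] = []
    run: list[int] = []
    for s in sites + [None]:  # sentinel flushes the last run
        if run and s is not None and s == run[-1] + 1:
            run.append(s)
            continue
        if len(run) - 1 >= min_len:
            first, last = run[0], run[-1]
            tags.append(
                SequenceTag(
                    start=first + 1,
                    end=last,
                    residues=sequence[first : last],
                    sites=tuple(run),
                )
            )
        run = [s] if s is not None else []
    return tags


def pair_heatmap(matches: list[FragmentMatch], sequence: str) -> np.ndarray:
    """20x20 matrix of summed normalized abundance by cleaved residue pair.

    Rows index the N-terminal residue of the cleaved bond, columns the
    C-terminal residue; abundance at site ``i`` accumulates into
    ``(sequence[i-1], sequence[i])``.  Totals match the pre-rescale site
    profile sums.
    """
    _require_normalized(matches)
    H = np.zeros((20, 20))
    L = len(sequence)
    for m in matches:
        if not (1 <= m.site <= L - 1):
            raise ValueError(f"site {m.site} outside 1..{L - 1}")
        r = _AA_INDEX[sequence[m.site - 1]]
        c = _AA_INDEX[sequence[m.site]]
        H[r, c] += m.normalized_intensity
    return H


@dataclass
class TopologyEnrichment:
    """Permutation test of abundance concentration inside TM helices."""

    tm_fraction: float
    p_value: float
    null_mean: float
    null_sd: float
    per_helix: dict[int, float]
    degenerate: bool = False


def _tm_site_mask(spec: ProteinSpec) -> np.ndarray:
    """Site i (bond between residues i and i+1) is TM iff residue i is in a helix."""
    L = len(spec.sequence)
    mask = np.zeros(L - 1, dtype=bool)
    for seg in spec.tm_segments():
        lo = max(1, seg.start)
        hi = min(L - 1, seg.end)
        mask[lo - 1 : hi] = True
    return mask


def topology_enrichment(
    profile: SiteProfile,
    spec: ProteinSpec,
    n_perm: int = 1000,
    seed: int = 0,
) -> TopologyEnrichment:
    """Circular-shift permutation test of TM-helix abundance enrichment.

    The observed statistic is the fraction of total abundance at sites
    inside TM helices.  The null preserves the autocorrelation of successive
    cleavages by circularly shifting the site-abundance vector by uniform
    random offsets.  p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    abund = profile.raw_abundance
    total = abund.sum()
    mask = _tm_site_mask(spec)
    per_helix: dict[int, float] = {}
    for seg in spec.tm_segments():
        lo = max(1, seg.start)
        hi = min(len(spec.sequence) - 1, seg.end)
        per_helix[seg.helix_index] = float(abund[lo - 1 : hi].sum())
    if total <= 0:
        return TopologyEnrichment(
            tm_fraction=0.0, p_value=1.0, null_mean=0.0, null_sd=0.0,
            per_helix=per_helix, degenerate=True,
        )
    observed = float(abund[mask].sum() / total)
    rng = np.random.default_rng(seed)
    n_sites = abund.size
    shifts = rng.integers(1, n_sites, size=n_perm)
    null = np.empty(n_perm)
    for k, sh in enumerate(shifts):
        null[k] = np.roll(abund, int(sh))[mask].sum() / total
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return TopologyEnrichment(
        tm_fraction=observed,
        p_value=p,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        per_helix=per_helix,
    )


def compare_modalities(
    matches_a: list[FragmentMatch],
    matches_b: list[FragmentMatch],
    L: int,
    labels: tuple[str, str] = ("IRMPD", "HCD"),
) -> dict[str, dict[str, float]]:
    """Per-modality mean fragment neutral mass, mean charge, and coverage.

    Means are unweighted over unique (site, ion_type, z) matches.
    """
    out: dict[str, dict[str, float]] = {}
    for label, matches in zip(labels, (matches_a, matches_b)):
        if not matches:
            raise ValueError(f"empty match set for {label}")
        uniq: dict[tuple[int, str, int], FragmentMatch] = {}
        for m in matches:
            uniq.setdefault(m.key(), m)
        masses = [m.fragment.neutral_mass for m in uniq.values()]
        charges = [m.z for m in uniq.values()]
        out[label] = {
            "mean_fragment_mass": float(np.mean(masses)),
            "mean_fragment_charge": float(np.mean(charges)),
            "coverage": coverage(matches, L),
            "n_unique": len(uniq),
        }
    return out
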