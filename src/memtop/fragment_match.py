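"""Match observed MS2 centroids to theoretical b/y fragments across charges.

Matching is a greedy global assignment: every in-tolerance (peak, admissible
fragment, charge) pair competes, candidates are sorted by |ppm error| (ties:
longer fragment first, then b before y), and each peak / each
(fragment, charge) target is consumed at most once.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .io import PeakList
from .masses_ions import TheoreticalFragment, mz

__all__ = [
    "FragmentMatch",
    "SiteEvidence",
    "match_fragments",
    "group_repeats",
    "complementary_pairs",
    "unique_fragment_counts",
]

DEFAULT_TOL_PPM = 10.0


@dataclass
class FragmentMatch:
    """An observed peak assigned to a theoretical fragment at a charge."""

    fragment: TheoreticalFragment
    z: int
    observed_mz: float
    ppm_error: float
    raw_intensity: float
    normalized_intensity: float | None = None  # filled by landscape.normalize_by_charge

    @property
    def site(self) -> int:
        return self.fragment.site

    @property
    def ion_type(self) -> str:
        return self.fragment.ion_type

    def key(self) -> tuple[int, str, int]:
        return (self.fragment.site, self.fragment.ion_type, self.z)


@dataclass
class SiteEvidence:
    """All matches sharing one cleavage site (repeat fragments grouped)."""

    site: int
    charge_states: set[int] = field(default_factory=set)
    ion_types: set[str] = field(default_factory=set)
    matches: list[FragmentMatch] = field(default_factory=list)

    @property
    def n_charge_states(self) -> int:
        return len(self.charge_states)


def match_fragments(
    peaks: PeakList,
    ladder: list[TheoreticalFragment],
    z_max: int,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> list[FragmentMatch]:
    """Assign peaks to admissible fragments over charges ``1..z_max``.

    All (peak, fragment, z) pairs within tolerance compete; assignments are
    made globally by smallest |ppm|, then larger fragment length, then b
    before y.  Inadmissible (disulfide-masked) fragments are never matched;
    no peak and no (fragment, z) target is consumed twice.
    """
    if len(peaks) == 0 or not ladder:
        return []
    # candidate rows: (abs_ppm, -length, ion_rank, site, z) key + peak index
    rows: list[tuple[tuple, int, int, TheoreticalFragment, float]] = []
    for frag in ladder:
        if not frag.admissible:
            continue
        ion_rank = 0 if frag.ion_type == "b" else 1
        for z in range(1, z_max + 1):
            target = mz(frag.neutral_mass, z)
            tol = target * tol_ppm * 1e-6
            lo = int(np.searchsorted(peaks.mz, target - tol, side="left"))
            hi = int(np.searchsorted(peaks.mz, target + tol, side="right"))
            for j in range(lo, hi):
                ppm = (peaks.mz[j] - target) / target * 1e6
                key = (abs(ppm), -frag.length, ion_rank, frag.site, z)
                rows.append((key, z, j, frag, ppm))

    rows.sort(key=lambda r: r[0])
    used_peaks: set[int] = set()
    used_targets: set[tuple[int, str, int]] = set()
    matches: list[FragmentMatch] = []
    for key, z, j, frag, ppm in rows:
        tkey = (frag.site, frag.ion_type, z)
        if j in used_peaks or tkey in used_targets:
            continue
        used_peaks.add(j)
        used_targets.add(tkey)
        matches.append(
            FragmentMatch(
                fragment=frag,
                z=z,
                observed_mz=float(peaks.mz[j]),
                ppm_error=float(ppm),
                raw_intensity=float(peaks.intensity[j]),
            )
        )
    matches.sort(key=lambda m: (m.site, m.ion_type, m.z))
    return matches


def group_repeats(matches: list[FragmentMatch]) -> list[SiteEvidence]:
    """Partition matches by cleavage site; repeat fragments share a site."""
    by_site: dict[int, SiteEvidence] = {}
    for m in matches:
        ev = by_site.setdefault(m.site, SiteEvidence(site=m.site))
        ev.charge_states.add(m.z)
        ev.ion_types.add(m.ion_type)
        ev.matches.append(m)
    return [by_site[s] for s in sorted(by_site)]


def complementary_pairs(
    matches: list[FragmentMatch], L: int
) -> list[tuple[int, list[FragmentMatch], list[FragmentMatch]]]:
    """Sites where both the b ion and its complementary y ion are matched.

    The y complement of b at site ``i`` has length ``L - i`` and shares the
    same site index.
    """
    b_by_site: dict[int, list[FragmentMatch]] = defaultdict(list)
    y_by_site: dict[int, list[FragmentMatch]] = defaultdict(list)
    for m in matches:
        (b_by_site if m.ion_type == "b" else y_by_site)[m.site].append(m)
    out = []
    for site in sorted(set(b_by_site) & set(y_by_site)):
        out.append((site, b_by_site[site], y_by_site[site]))
    return out


def unique_fragment_counts(matches: list[FragmentMatch]) -> dict[str, int]:
    """Both plausible 'unique fragment' counts: by site+type and site+type+charge."""
    return {
        "by_site_type": len({(m.site, m.ion_type) for m in matches}),
        "by_site_type_charge": len({(m.site, m.ion_type, m.z) for m in matches}),
    }
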