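"""Mass arithmetic and disulfide-constrained theoretical b/y fragment ladders.

Conventions used throughout the package:

* Intact (MS1) masses are computed on the *average* mass scale; fragment
  (MS2) masses on the *monoisotopic* scale.
* A protein of length ``L`` has ``L - 1`` cleavage sites; site ``i`` is the
  peptide bond between residues ``i`` and ``i + 1`` (1-based).
* Only b- and y-type ions are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from Bio.Data import IUPACData

__all__ = [
    "PROTON_MASS",
    "WATER_MONO",
    "WATER_AVG",
    "DISULFIDE_DECREMENT",
    "RESIDUE_MASSES",
    "MassScale",
    "Segment",
    "ProteinSpec",
    "TheoreticalFragment",
    "peptide_mass",
    "apply_disulfides",
    "mz",
    "neutral_mass_from_mz",
    "fragment_ladder",
    "masked_sites",
]

MassScale = Literal["mono", "avg"]

PROTON_MASS = 1.007276
WATER_MONO = 18.010565
WATER_AVG = 18.0153

#: Mass removed per disulfide bond (loss of two hydrogens).
DISULFIDE_DECREMENT: dict[str, float] = {"mono": 2.015650, "avg": 2.01588}

_WATER = {"mono": WATER_MONO, "avg": WATER_AVG}

# Residue masses derived from the IUPAC free amino-acid weights by removing
# one water (condensation).
RESIDUE_MASSES: dict[str, dict[str, float]] = {
    aa: {
        "mono": IUPACData.monoisotopic_protein_weights[aa] - WATER_MONO,
        "avg": IUPACData.protein_weights[aa] - WATER_AVG,
    }
    for aa in "ACDEFGHIKLMNPQRSTVWY"
}


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in RESIDUE_MASSES:
            raise ValueError(f"unknown residue symbol {aa!r} at position {pos}")


def _check_scale(scale: str) -> None:
    if scale not in ("mono", "avg"):
        raise ValueError(f"scale must be 'mono' or 'avg', got {scale!r}")


def peptide_mass(sequence: str, scale: MassScale = "mono") -> float:
    """Neutral mass of a linear peptide: sum of residue masses plus water.

    Parameters
    ----------
    sequence
        Residue string over the 20 canonical amino acids.
    scale
        ``"mono"`` for monoisotopic, ``"avg"`` for average masses.
    """
    _check_sequence(sequence)
    _check_scale(scale)
    return sum(RESIDUE_MASSES[aa][scale] for aa in sequence) + _WATER[scale]


def apply_disulfides(neutral_mass: float, n_bonds: int, scale: MassScale = "avg") -> float:
    """Correct a neutral mass for ``n_bonds`` disulfide bridges (−2 H each)."""
    if n_bonds < 0:
        raise ValueError("n_bonds must be >= 0")
    _check_scale(scale)
    out = neutral_mass - n_bonds * DISULFIDE_DECREMENT[scale]
    if out <= 0:
        raise ValueError(
            f"disulfide correction gives non-positive mass ({out:.3f} Da)"
        )
    return out


def mz(neutral_mass: float, z: int) -> float:
    """m/z of a protonated species: ``(M + z * proton) / z``."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + z * PROTON_MASS) / z


def neutral_mass_from_mz(mz_value: float, z: int) -> float:
    """Invert :func:`mz`: ``z * (mz - proton)``."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    if mz_value <= PROTON_MASS:
        raise ValueError(f"m/z {mz_value} is not above the proton mass")
    return z * (mz_value - PROTON_MASS)


@dataclass(frozen=True)
class Segment:
    """A topology segment: 1-based inclusive residue span of a given kind."""

    start: int
    end: int
    kind: Literal["TM_helix", "loop_out", "loop_in", "terminus"]
    helix_index: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad segment span {self.start}..{self.end}")
        if self.kind not in ("TM_helix", "loop_out", "loop_in", "terminus"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.kind == "TM_helix" and self.helix_index is None:
            raise ValueError("TM_helix segments need a helix_index")

    def __contains__(self, residue: int) -> bool:
        return self.start <= residue <= self.end


@dataclass
class ProteinSpec:
    """Protein description: sequence plus topology/disulfide/oligomer annotation.

    Serves both as the ground truth for simulation and as annotation for
    analysis.  ``helix_stability`` maps helix index to a weight in ``[0, 1]``
    standing in for per-helix gas-phase structural persistence.
    """

    id: str
    sequence: str
    oligomer_count: int = 1
    topology: list[Segment] = field(default_factory=list)
    disulfides: list[tuple[int, int]] = field(default_factory=list)
    helix_stability: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        if self.oligomer_count < 1:
            raise ValueError("oligomer_count must be >= 1")
        L = len(self.sequence)
        if self.topology:
            segs = sorted(self.topology, key=lambda s: s.start)
            cursor = 1
            for seg in segs:
                if seg.start != cursor:
                    raise ValueError(
                        f"topology gap/overlap at residue {cursor} (segment starts {seg.start})"
                    )
                cursor = seg.end + 1
            if cursor != L + 1:
                raise ValueError(f"topology covers 1..{cursor - 1}, sequence length {L}")
            self.topology = segs
        seen: set[int] = set()
        pairs: list[tuple[int, int]] = []
        for pair in self.disulfides:
            i, j = sorted(pair)
            if not (1 <= i < j <= L):
                raise ValueError(f"disulfide pair {pair} out of range 1..{L}")
            if self.sequence[i - 1] != "C" or self.sequence[j - 1] != "C":
                raise ValueError(f"disulfide pair {pair} does not point at cysteines")
            if i in seen or j in seen:
                raise ValueError(f"residue reused across disulfide pairs: {pair}")
            seen.update((i, j))
            pairs.append((i, j))
        self.disulfides = pairs
        for h, w in self.helix_stability.items():
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"helix_stability[{h}]={w} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_sites(self) -> int:
        return len(self.sequence) - 1

    def subunit_mass(self, scale: MassScale = "avg") -> float:
        """Neutral mass of one subunit including disulfide correction."""
        return apply_disulfides(
            peptide_mass(self.sequence, scale), len(self.disulfides), scale
        )

    def intact_mass(self, scale: MassScale = "avg") -> float:
        """Neutral mass of the oligomeric precursor."""
        return self.oligomer_count * self.subunit_mass(scale)

    def tm_segments(self) -> list[Segment]:
        return [s for s in self.topology if s.kind == "TM_helix"]

    def helix_of_residue(self, residue: int) -> int | None:
        for seg in self.topology:
            if seg.kind == "TM_helix" and residue in seg:
                return seg.helix_index
        return None

    def stability_at(self, residue: int) -> float:
        h = self.helix_of_residue(residue)
        if h is None:
            return 0.0
        return self.helix_stability.get(h, 0.0)


@dataclass(frozen=True)
class TheoreticalFragment:
    """A b- or y-type fragment from a single backbone cleavage.

    ``admissible`` is False exactly when the cleavage would put one cysteine
    of a disulfide pair on the fragment and its partner on the complement
    (the fragment cannot detach as a simple b/y ion).
    """

    ion_type: Literal["b", "y"]
    site: int
    length: int
    neutral_mass: float
    admissible: bool = True

    def label(self) -> str:
        return f"{self.ion_type}{self.length}"


def masked_sites(disulfides: Sequence[tuple[int, int]]) -> set[int]:
    """Sites whose cleavage separates the two cysteines of some disulfide.

    Site ``i`` splits the chain into 1..i and i+1..L, so pair ``(a, b)``
    (a < b) is broken exactly when ``a <= i < b``.
    """
    out: set[int] = set()
    for a, b in (tuple(sorted(p)) for p in disulfides):
        out.update(range(a, b))
    return out


def fragment_ladder(spec: ProteinSpec, scale: MassScale = "mono") -> list[TheoreticalFragment]:
    """Generate all 2(L−1) theoretical b/y fragments for one subunit.

    b_i covers residues 1..i (no water); y_j covers residues L−j+1..L plus
    water.  Inadmissible fragments (disulfide-split cleavages) are flagged,
    not dropped.  Admissible fragments that fully contain ``k`` intact
    disulfide bonds carry a ``−k × 2H`` correction.
    """
    _check_scale(scale)
    seq = spec.sequence
    L = len(seq)
    if L < 2:
        raise ValueError("need at least 2 residues to fragment")
    water = _WATER[scale]
    decr = DISULFIDE_DECREMENT[scale]
    pairs = [tuple(sorted(p)) for p in spec.disulfides]
    masked = masked_sites(pairs)

    # prefix[i] = sum of residue masses 1..i
    prefix = [0.0] * (L + 1)
    for i, aa in enumerate(seq, start=1):
        prefix[i] = prefix[i - 1] + RESIDUE_MASSES[aa][scale]

    frags: list[TheoreticalFragment] = []
    for site in range(1, L):
        ok = site not in masked
        b_bonds = sum(1 for a, b in pairs if b <= site) if ok else 0
        y_bonds = sum(1 for a, b in pairs if a > site) if ok else 0
        b_mass = prefix[site] - b_bonds * decr
        y_mass = prefix[L] - prefix[site] + water - y_bonds * decr
        frags.append(TheoreticalFragment("b", site, site, b_mass, ok))
        frags.append(TheoreticalFragment("y", site, L - site, y_mass, ok))
    return frags
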