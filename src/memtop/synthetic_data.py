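"""Seeded generators of protein specs and MS1/MS2 peak lists with ground truth.

The MS1 generator emulates multi-charge series of an intact (possibly
oligomeric) membrane protein carrying phospholipid-adduct ladders and
residual detergent adducts whose persistence follows a sigmoidal
power x time removal model.  The MS2 generator emits b/y fragments whose
per-site probabilities follow residue-pair propensities, per-helix stability
weights and mobile-proton availability, with disulfide-masked sites silenced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .io import PeakList
from .masses_ions import (
    ProteinSpec,
    Segment,
    TheoreticalFragment,
    fragment_ladder,
    mz,
)

__all__ = [
    "LipidConfig",
    "RemovalConfig",
    "DetergentConfig",
    "MS1Config",
    "ActivationPreset",
    "MS2Config",
    "SimConfig",
    "EmittedFragment",
    "GroundTruth",
    "DETERGENT_PRESETS",
    "ACTIVATION_PRESETS",
    "make_protein",
    "simulate_ms1",
    "simulate_ms2",
    "residual_adduct_mean",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LipidConfig:
    """Phospholipid adduct ladder: fixed spacing, geometric abundance decay."""

    mass: float = 720.0          # Da, inside the 700-730 Da phospholipid window
    max_count: int = 5
    abundance_decay: float = 0.45  # share of step k is decay**k


@dataclass(frozen=True)
class RemovalConfig:
    """Sigmoidal detergent-removal model in laser power x scaled time.

    Mean residual adduct count per ion:

        mu(P, t) = residual_mean_max / (1 + exp(steepness * (P * t/time_scale - power_half)))

    which is monotone non-increasing in both power and irradiation time.
    """

    power_half: float = 3.6      # W at the reference irradiation time
    steepness: float = 25.0      # per W; abrupt adducted -> bare transition
    time_scale: float = 200.0    # ms; reference irradiation time
    residual_mean_max: float = 8.0


@dataclass(frozen=True)
class DetergentConfig:
    mass: float = 510.62         # Da per adduct (DDM)
    removal: RemovalConfig = field(default_factory=RemovalConfig)


#: Per-detergent presets; power_half values are the minimum powers at 200 ms.
DETERGENT_PRESETS: dict[str, DetergentConfig] = {
    "C8E4": DetergentConfig(mass=306.44, removal=RemovalConfig(power_half=2.4)),
    "G1": DetergentConfig(mass=500.0, removal=RemovalConfig(power_half=3.0)),
    "DDM": DetergentConfig(mass=510.62, removal=RemovalConfig(power_half=3.6)),
}


@dataclass(frozen=True)
class MS1Config:
    z_coef: float = 0.0778       # z_avg = z_coef * sqrt(M), Rayleigh-limit heuristic
    z_spread: float = 1.2        # stdev in charges
    n_ions: int = 2000
    lipid: LipidConfig = field(default_factory=LipidConfig)
    detergent: DetergentConfig = field(default_factory=DetergentConfig)


@dataclass(frozen=True)
class ActivationPreset:
    """Modality knobs: HCD yields lower fragment charge and smaller fragments."""

    charge_scale: float
    size_decay: float


ACTIVATION_PRESETS: dict[str, ActivationPreset] = {
    "IRMPD": ActivationPreset(charge_scale=0.80, size_decay=0.0),
    "HCD": ActivationPreset(charge_scale=0.50, size_decay=3.0),
}


def _default_pair_weights() -> dict[str, float]:
    # charge-remote X|P and D|X / E|X plus the N-terminal-to-glycine family
    return {
        "T|P": 10.0,
        "I|P": 8.0,
        "L|P": 6.0,
        "X|P": 5.0,
        "A|G": 8.0,
        "F|G": 6.0,
        "V|G": 6.0,
        "I|G": 5.0,
        "D|X": 4.0,
        "E|X": 3.0,
    }


@dataclass(frozen=True)
class MS2Config:
    pair_weights: dict[str, float] = field(default_factory=_default_pair_weights)
    default_pair_weight: float = 1.0
    helix_weight_scale: float = 4.0
    loop_basic_residue_penalty: float = 0.25
    basic_radius: int = 2        # residues around the bond scanned for R/K
    min_propensity_floor: float = 0.05
    n_fragments: int = 250
    complementary_prob: float = 0.3
    intensity_sigma: float = 0.35  # lognormal jitter on true intensities


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    resolution_fwhm: float = 0.05  # Th at ref_mz; 0 disables centroid jitter
    ref_mz: float = 2000.0
    noise_peak_rate: float = 1.0   # peaks per 1000 Th
    noise_intensity_scale: float = 0.01  # fraction of max signal
    ms1: MS1Config = field(default_factory=MS1Config)
    ms2: MS2Config = field(default_factory=MS2Config)

    def noiseless(self) -> "SimConfig":
        """Zero-jitter, zero-noise variant for exact-recovery tests."""
        return replace(self, resolution_fwhm=0.0, noise_peak_rate=0.0)


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EmittedFragment:
    site: int
    ion_type: Literal["b", "y"]
    charge: int
    true_intensity: float
    neutral_mass: float
    mz_true: float


@dataclass
class GroundTruth:
    """Recovery-test oracle emitted alongside every simulated spectrum."""

    propensity: np.ndarray | None = None  # per-site, sums to 1 over admissible
    fragments: list[EmittedFragment] = field(default_factory=list)
    ms1_species: list[dict] = field(default_factory=list)
    mobile_protons: int | None = None
    residual_adduct_mean: float | None = None

    def fragment_keys(self) -> set[tuple[int, str, int]]:
        return {(f.site, f.ion_type, f.charge) for f in self.fragments}

    def emitted_sites(self) -> set[int]:
        return {f.site for f in self.fragments}


# --------------------------------------------------------------------------
# protein construction
# --------------------------------------------------------------------------

_HELIX_ALPHABET = "ALIVFMWGPST"
_LOOP_ALPHABET = "GSTNQDERKHAP"


def _helix_weights(gly_freq: float, pro_freq: float) -> np.ndarray:
    base = {
        "A": 0.15, "L": 0.20, "I": 0.13, "V": 0.13, "F": 0.10,
        "M": 0.05, "W": 0.03, "S": 0.05, "T": 0.06,
    }
    scale = (1.0 - gly_freq - pro_freq) / sum(base.values())
    w = [base.get(a, 0.0) * scale for a in _HELIX_ALPHABET]
    w[_HELIX_ALPHABET.index("G")] = gly_freq
    w[_HELIX_ALPHABET.index("P")] = pro_freq
    return np.array(w)


_LOOP_WEIGHTS = np.array(
    [0.08, 0.10, 0.08, 0.08, 0.06, 0.10, 0.10, 0.12, 0.10, 0.04, 0.06, 0.08]
)


def make_protein(
    n_helices: int,
    helix_len: int = 24,
    loop_len: int = 12,
    n_disulfides: int = 0,
    stability_profile: list[float] | None = None,
    seed: int = 0,
    oligomer_count: int = 1,
    gly_freq: float = 0.09,
    pro_freq: float = 0.04,
    spec_id: str | None = None,
) -> ProteinSpec:
    """Construct a synthetic polytopic membrane protein.

    Topology alternates loops and TM helices, starting and ending with a
    loop (``n_helices`` helices, ``n_helices + 1`` loops; loops alternate
    out/in starting extracellular).  Helices are enriched in hydrophobic
    residues with configurable G/P frequency; basic residues go
    preferentially to loops; disulfide cysteine pairs are placed in
    extracellular (``loop_out``) loops.  Deterministic under ``seed``.
    """
    if n_helices < 1 or helix_len < 1 or loop_len < 1:
        raise ValueError("n_helices, helix_len and loop_len must be >= 1")
    rng = np.random.default_rng(seed)
    hw = _helix_weights(gly_freq, pro_freq)
    lw = _LOOP_WEIGHTS / _LOOP_WEIGHTS.sum()

    residues: list[str] = []
    segments: list[Segment] = []
    pos = 1
    for h in range(n_helices + 1):
        kind = "loop_out" if h % 2 == 0 else "loop_in"
        residues.extend(rng.choice(list(_LOOP_ALPHABET), size=loop_len, p=lw))
        segments.append(Segment(pos, pos + loop_len - 1, kind))
        pos += loop_len
        if h < n_helices:
            residues.extend(rng.choice(list(_HELIX_ALPHABET), size=helix_len, p=hw))
            segments.append(Segment(pos, pos + helix_len - 1, "TM_helix", helix_index=h + 1))
            pos += helix_len

    # disulfides bridge cysteine pairs inside extracellular loops; keeping a
    # pair within one loop bounds the masked-site span to that loop
    free: dict[int, list[int]] = {
        idx: list(range(s.start, s.end + 1))
        for idx, s in enumerate(segments)
        if s.kind == "loop_out"
    }
    disulfides = []
    for _ in range(n_disulfides):
        eligible = [idx for idx, pool in free.items() if len(pool) >= 2]
        if not eligible:
            raise ValueError(
                f"cannot place {n_disulfides} disulfide pairs in the "
                "available extracellular-loop residues"
            )
        seg_idx = int(rng.choice(eligible))
        pool = free[seg_idx]
        picked = sorted(rng.choice(len(pool), size=2, replace=False))
        i, j = pool[picked[0]], pool[picked[1]]
        for p in sorted(picked, reverse=True):
            pool.pop(p)
        residues[i - 1] = "C"
        residues[j - 1] = "C"
        disulfides.append((i, j))
    disulfides.sort()

    if stability_profile is None:
        stability = {h + 1: 0.5 for h in range(n_helices)}
    else:
        if len(stability_profile) != n_helices:
            raise ValueError("stability_profile length must equal n_helices")
        stability = {h + 1: float(w) for h, w in enumerate(stability_profile)}

    return ProteinSpec(
        id=spec_id or f"synthetic-{n_helices}tm-{seed}",
        sequence="".join(residues),
        oligomer_count=oligomer_count,
        topology=segments,
        disulfides=disulfides,
        helix_stability=stability,
    )


# --------------------------------------------------------------------------
# MS1 simulation
# --------------------------------------------------------------------------

def residual_adduct_mean(power: float, time_ms: float, removal: RemovalConfig) -> float:
    """Expected residual detergent adducts per ion at a power/time setting."""
    dose = power * (time_ms / removal.time_scale)
    x = removal.steepness * (dose - removal.power_half)
    # clip to avoid overflow in exp for extreme settings
    return removal.residual_mean_max / (1.0 + math.exp(min(max(x, -60.0), 60.0)))


def _centroid_jitter(rng: np.random.Generator, mz_true: np.ndarray, config: SimConfig) -> np.ndarray:
    if config.resolution_fwhm <= 0:
        return mz_true
    sigma = (config.resolution_fwhm / 2.3548) * (mz_true / config.ref_mz)
    return mz_true + rng.normal(0.0, 1.0, size=mz_true.shape) * sigma


def _noise_peaks(
    rng: np.random.Generator, lo: float, hi: float, max_signal: float, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    if config.noise_peak_rate <= 0 or hi <= lo:
        return np.empty(0), np.empty(0)
    n = rng.poisson(config.noise_peak_rate * (hi - lo) / 1000.0)
    if n == 0:
        return np.empty(0), np.empty(0)
    mzs = rng.uniform(lo, hi, size=n)
    ints = rng.exponential(config.noise_intensity_scale * max_signal, size=n) + 1e-9
    return mzs, ints


def simulate_ms1(
    spec: ProteinSpec,
    power: float,
    time_ms: float,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> tuple[PeakList, GroundTruth]:
    """Simulate an MS1 spectrum of the intact (oligomeric) precursor.

    Charges are drawn around ``z_coef * sqrt(M)``; each ion carries a
    geometric number of residual detergent adducts (mean set by the removal
    model) and up to ``max_count`` lipid adducts with geometrically decaying
    abundance.  Species are centroided with resolution-dependent Gaussian
    jitter and uniform noise peaks are added.
    """
    if power < 0 or time_ms <= 0:
        raise ValueError("power must be >= 0 and time_ms > 0")
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ms1 = config.ms1

    mass = spec.intact_mass("avg")
    z_avg = ms1.z_coef * math.sqrt(mass)
    z = np.maximum(1, np.rint(rng.normal(z_avg, ms1.z_spread, size=ms1.n_ions)).astype(int))

    mu = residual_adduct_mean(power, time_ms, ms1.detergent.removal)
    p_geom = 1.0 / (1.0 + mu)
    n_det = rng.geometric(p_geom, size=ms1.n_ions) - 1

    k = np.arange(ms1.lipid.max_count + 1)
    lipid_p = ms1.lipid.abundance_decay ** k
    lipid_p /= lipid_p.sum()
    n_lip = rng.choice(k, size=ms1.n_ions, p=lipid_p)

    species: dict[tuple[int, int, int], int] = {}
    for zi, nl, nd in zip(z, n_lip, n_det):
        key = (int(zi), int(nl), int(nd))
        species[key] = species.get(key, 0) + 1

    records = []
    mz_true = []
    intensity = []
    for (zi, nl, nd), count in sorted(species.items()):
        m = mass + nl * ms1.lipid.mass + nd * ms1.detergent.mass
        m_over_z = mz(m, zi)
        records.append(
            {"z": zi, "n_lipid": nl, "n_detergent": nd, "mz_true": m_over_z,
             "neutral_mass": m, "count": count}
        )
        mz_true.append(m_over_z)
        intensity.append(float(count))
    mz_true = np.array(mz_true)
    intensity = np.array(intensity)

    mz_obs = _centroid_jitter(rng, mz_true, config)
    lo, hi = mz_obs.min() - 100.0, mz_obs.max() + 100.0
    noise_mz, noise_int = _noise_peaks(rng, lo, hi, intensity.max(), config)

    peaks = PeakList(
        np.concatenate([mz_obs, noise_mz]),
        np.concatenate([intensity, noise_int]),
        metadata={
            "ms_level": 1,
            "activation": "IR",
            "power_W": power,
            "time_ms": time_ms,
            "precursor_mass": mass,
        },
    )
    truth = GroundTruth(ms1_species=records, residual_adduct_mean=float(n_det.mean()))
    return peaks, truth


# --------------------------------------------------------------------------
# MS2 simulation
# --------------------------------------------------------------------------

def site_propensities(spec: ProteinSpec, config: MS2Config) -> np.ndarray:
    """Per-site cleavage propensity vector (normalized; masked sites zero).

    p_i is proportional to pair_weight(a_i | a_{i+1}) times a helix-stability
    boost times a mobile-proton access factor that penalizes sites flanked by
    basic residues, floored at ``min_propensity_floor``.
    """
    seq = spec.sequence
    L = len(seq)
    weights = np.empty(L - 1)
    for i in range(1, L):
        n_res, c_res = seq[i - 1], seq[i]
        pw = config.pair_weights
        w = pw.get(
            f"{n_res}|{c_res}",
            pw.get(f"X|{c_res}", pw.get(f"{n_res}|X", config.default_pair_weight)),
        )
        w *= 1.0 + config.helix_weight_scale * spec.stability_at(i)
        lo = max(1, i - config.basic_radius + 1)
        hi = min(L, i + config.basic_radius)
        if any(seq[j - 1] in "RK" for j in range(lo, hi + 1)):
            w *= config.loop_basic_residue_penalty
        weights[i - 1] = max(w, config.min_propensity_floor)

    from .masses_ions import masked_sites

    for site in masked_sites(spec.disulfides):
        weights[site - 1] = 0.0
    total = weights.sum()
    if total <= 0:
        raise ValueError("all cleavage sites are disulfide-masked")
    return weights / total


def simulate_ms2(
    spec: ProteinSpec,
    precursor_z: int,
    activation: str = "IRMPD",
    config: SimConfig | None = None,
    seed: int | None = None,
) -> tuple[PeakList, GroundTruth]:
    """Simulate an MS2 fragment spectrum of one subunit at ``precursor_z``.

    Fragments are sampled from the site-propensity vector with a
    modality-dependent size bias (HCD disfavors long fragments), charges are
    partitioned roughly proportionally to fragment length (HCD drawing lower
    charge), complementary b/y partners are co-emitted with configurable
    probability, and disulfide-masked sites are never emitted.
    """
    if precursor_z < 2:
        raise ValueError("precursor_z must be >= 2 to partition charge")
    if activation not in ACTIVATION_PRESETS:
        raise ValueError(f"unknown activation {activation!r}; use IRMPD or HCD")
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ms2 = config.ms2
    preset = ACTIVATION_PRESETS[activation]

    seq = spec.sequence
    L = len(seq)
    prop = site_propensities(spec, ms2)
    ladder = fragment_ladder(spec, "mono")
    by_key: dict[tuple[str, int], TheoreticalFragment] = {
        (f.ion_type, f.site): f for f in ladder
    }

    n_basic = sum(seq.count(a) for a in "RKH")
    mobile = max(1, precursor_z - n_basic)

    # joint (site, ion_type) selection weights with modality size bias
    sites = np.arange(1, L)
    sel = np.empty((L - 1, 2))  # columns: b, y
    for col, ion in enumerate("by"):
        length = sites if ion == "b" else L - sites
        sel[:, col] = prop * np.exp(-preset.size_decay * length / L)
    sel_flat = sel.ravel()
    total = sel_flat.sum()
    sel_flat = sel_flat / total

    def draw_charge(length: int) -> int:
        q = min(max(preset.charge_scale * length / L, 0.02), 0.98)
        return 1 + int(rng.binomial(precursor_z - 2, q)) if precursor_z > 2 else 1

    emitted: dict[tuple[int, str, int], float] = {}
    picks = rng.choice(sel_flat.size, size=ms2.n_fragments, p=sel_flat)
    for pick in picks:
        site = int(pick // 2) + 1
        ion = "by"[int(pick % 2)]
        members = [(site, ion)]
        if rng.random() < ms2.complementary_prob:
            members.append((site, "y" if ion == "b" else "b"))
        for s, it in members:
            frag = by_key[(it, s)]
            zf = draw_charge(frag.length)
            base = 100.0 * prop[s - 1] / prop.max()
            inten = base * rng.lognormal(0.0, ms2.intensity_sigma)
            key = (s, it, zf)
            emitted[key] = emitted.get(key, 0.0) + inten

    records: list[EmittedFragment] = []
    mz_true = []
    intensity = []
    for (s, it, zf), inten in sorted(emitted.items()):
        frag = by_key[(it, s)]
        m_over_z = mz(frag.neutral_mass, zf)
        records.append(EmittedFragment(s, it, zf, inten, frag.neutral_mass, m_over_z))
        mz_true.append(m_over_z)
        # image-current response scales with charge
        intensity.append(inten * zf)
    mz_true = np.array(mz_true)
    intensity = np.array(intensity)

    mz_obs = _centroid_jitter(rng, mz_true, config)
    lo, hi = mz_obs.min() - 100.0, mz_obs.max() + 100.0
    noise_mz, noise_int = _noise_peaks(rng, lo, hi, intensity.max(), config)

    precursor_mass = spec.intact_mass("avg")
    peaks = PeakList(
        np.concatenate([mz_obs, noise_mz]),
        np.concatenate([intensity, noise_int]),
        metadata={
            "ms_level": 2,
            "activation": activation,
            "precursor_z": precursor_z,
            "precursor_mz": mz(precursor_mass, precursor_z),
        },
    )
    truth = GroundTruth(propensity=prop, fragments=records, mobile_protons=mobile)
    return peaks, truth
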