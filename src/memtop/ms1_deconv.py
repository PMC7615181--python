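"""Intact-mass inference from multi-charge peak series and adduct ladders.

A deliberately simple grid-search deconvolution: candidate neutral masses
are scored by the summed intensity of peaks falling within an m/z tolerance
of the predicted charge series, requiring a contiguous run of at least
``min_run`` charges.  Matched peaks then refine the mass estimate by a
weighted average of ``z * (mz_obs - proton)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PeakList
from .masses_ions import PROTON_MASS, mz

__all__ = [
    "ChargeSeriesFit",
    "AdductLadder",
    "fit_charge_series",
    "detect_adduct_ladder",
    "resolved_fraction",
]

DEFAULT_MZ_TOL = 0.5  # Th; native membrane-protein peaks are broad
MIN_RUN = 3           # contiguous charges needed to accept a series


@dataclass
class ChargeSeriesFit:
    """One charge-state series explained by a single neutral mass."""

    neutral_mass: float
    z_range: tuple[int, int]
    matched: list[dict] = field(default_factory=list)  # per-charge records
    score: float = 0.0            # summed matched intensity
    intensity_fraction: float = 0.0

    @property
    def charges(self) -> list[int]:
        return [m["z"] for m in self.matched]


@dataclass
class AdductLadder:
    """Satellite series at fixed mass increments above a base series."""

    base_mass: float
    spacing: float
    max_count: int
    step_masses: list[float] = field(default_factory=list)
    step_intensities: list[float] = field(default_factory=list)


def _nearest_within(peaks: PeakList, target: float, tol: float) -> int | None:
    """Index of the nearest peak within ``tol`` of ``target``, else None."""
    idx = int(np.searchsorted(peaks.mz, target))
    best = None
    best_d = tol
    for j in (idx - 1, idx):
        if 0 <= j < len(peaks):
            d = abs(peaks.mz[j] - target)
            if d <= best_d:
                best_d = d
                best = j
    return best


def _series_match(
    peaks: PeakList, mass: float, z_lo: int, z_hi: int, tol: float
) -> list[dict]:
    out = []
    for z in range(z_lo, z_hi + 1):
        pred = mz(mass, z)
        j = _nearest_within(peaks, pred, tol)
        if j is not None:
            out.append(
                {
                    "z": z,
                    "predicted_mz": pred,
                    "observed_mz": float(peaks.mz[j]),
                    "intensity": float(peaks.intensity[j]),
                }
            )
    return out


def _best_run(matched: list[dict], min_run: int) -> list[dict]:
    """Highest-intensity run of contiguous charges of length >= min_run."""
    best: list[dict] = []
    best_score = 0.0
    run: list[dict] = []
    for rec in matched:
        if run and rec["z"] == run[-1]["z"] + 1:
            run.append(rec)
        else:
            run = [rec]
        if len(run) >= min_run:
            score = sum(r["intensity"] for r in run)
            if score > best_score:
                best_score = score
                best = list(run)
    return best


def _refine_mass(run: list[dict]) -> float:
    w = np.array([r["intensity"] for r in run])
    m = np.array([r["z"] * (r["observed_mz"] - PROTON_MASS) for r in run])
    return float(np.average(m, weights=w))


def fit_charge_series(
    peaks: PeakList,
    mass_range: tuple[float, float],
    z_range: tuple[int, int] = (5, 30),
    mz_tol: float = DEFAULT_MZ_TOL,
    min_run: int = MIN_RUN,
    max_fits: int = 10,
) -> list[ChargeSeriesFit]:
    """Grid-search charge-series deconvolution.

    Candidate masses stepped at ``mz_tol / 2 * z_min`` are scored by the
    summed intensity of peaks within ``mz_tol`` of the predicted series over
    the best contiguous charge run of length >= ``min_run``; each surviving
    candidate is refined from its matched peaks, and near-duplicate fits
    (within ``2 * mz_tol * z_min``) are deduplicated keeping the higher
    score.  Returns fits sorted by score, best first.
    """
    if len(peaks) < min_run:
        return []
    lo, hi = mass_range
    if hi <= lo:
        raise ValueError("mass_range must be non-empty")
    z_lo, z_hi = z_range
    step = mz_tol / 2.0 * z_lo
    candidates = np.arange(lo, hi + step, step)

    total = peaks.total_intensity
    raw_fits: list[ChargeSeriesFit] = []
    for mass in candidates:
        matched = _series_match(peaks, float(mass), z_lo, z_hi, mz_tol)
        run = _best_run(matched, min_run)
        if not run:
            continue
        refined = _refine_mass(run)
        # re-match at the refined mass to stabilize the reported series
        run2 = _best_run(_series_match(peaks, refined, z_lo, z_hi, mz_tol), min_run)
        if run2:
            refined = _refine_mass(run2)
            run = run2
        score = sum(r["intensity"] for r in run)
        raw_fits.append(
            ChargeSeriesFit(
                neutral_mass=refined,
                z_range=(run[0]["z"], run[-1]["z"]),
                matched=run,
                score=score,
                intensity_fraction=score / total if total > 0 else 0.0,
            )
        )

    raw_fits.sort(key=lambda f: f.score, reverse=True)
    kept: list[ChargeSeriesFit] = []
    dedup_window = 2.0 * mz_tol * z_lo
    for fit in raw_fits:
        if all(abs(fit.neutral_mass - k.neutral_mass) > dedup_window for k in kept):
            kept.append(fit)
        if len(kept) >= max_fits:
            break
    return kept


def detect_adduct_ladder(
    peaks: PeakList,
    base_fit: ChargeSeriesFit,
    spacing_window: tuple[float, float],
    max_steps: int = 5,
    mz_tol: float = DEFAULT_MZ_TOL,
    min_run: int = MIN_RUN,
) -> AdductLadder | None:
    """Find a satellite series at ``base_mass + k * s`` for s in the window.

    Candidate spacings are scored jointly over all ladder steps (the true
    spacing explains several satellite series at once, which suppresses
    accidental single-step alignments); each matched step mass is then
    refined from its peaks and the reported spacing is the
    intensity-weighted mean of successive step differences.
    """
    s_lo, s_hi = spacing_window
    if s_hi <= s_lo:
        raise ValueError("spacing_window must be non-empty")
    z_lo, z_hi = base_fit.z_range
    z_lo = max(1, z_lo - 1)
    z_hi = z_hi + 1
    # fine enough that the k-th step stays within tolerance across the scan
    ds = max(mz_tol * z_lo / (2.0 * max_steps), 0.25)

    def step_runs(spacing: float) -> list[list[dict]]:
        runs = []
        for k in range(1, max_steps + 1):
            mass = base_fit.neutral_mass + k * spacing
            run = _best_run(_series_match(peaks, mass, z_lo, z_hi, mz_tol), min_run)
            if not run:
                break
            runs.append(run)
        return runs

    best_runs: list[list[dict]] = []
    best_score = 0.0
    for s in np.arange(s_lo, s_hi + ds, ds):
        runs = step_runs(float(s))
        score = sum(r["intensity"] for run in runs for r in run)
        if score > best_score:
            best_score = score
            best_runs = runs
    if not best_runs:
        return None

    step_masses = [_refine_mass(run) for run in best_runs]
    step_ints = [sum(r["intensity"] for r in run) for run in best_runs]

    diffs = np.diff(np.concatenate([[base_fit.neutral_mass], step_masses]))
    weights = np.array(step_ints)
    spacing = float(np.average(diffs, weights=weights))
    return AdductLadder(
        base_mass=base_fit.neutral_mass,
        spacing=spacing,
        max_count=len(step_masses),
        step_masses=step_masses,
        step_intensities=step_ints,
    )


def resolved_fraction(
    peaks: PeakList, fit: ChargeSeriesFit, mz_tol: float = DEFAULT_MZ_TOL
) -> float:
    """Fraction of total intensity on the bare-protein predicted series.

    Intensity within ``mz_tol`` of ``mz(fit.neutral_mass, z)`` over the
    fitted charge span counts as resolved; adduct satellites and noise do
    not.  Used to score spectrum quality as a function of activation.
    """
    total = peaks.total_intensity
    if total <= 0:
        return 0.0
    z_lo, z_hi = fit.z_range
    resolved = 0.0
    used: set[int] = set()
    for z in range(z_lo, z_hi + 1):
        j = _nearest_within(peaks, mz(fit.neutral_mass, z), mz_tol)
        if j is not None and j not in used:
            used.add(j)
            resolved += float(peaks.intensity[j])
    return resolved / total
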