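"""File I/O: peak lists (TSV + JSON sidecar), FASTA sequences, topology JSON."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
from Bio import SeqIO

from .masses_ions import ProteinSpec, Segment

__all__ = [
    "PeakList",
    "read_peaks",
    "write_peaks",
    "read_fasta",
    "read_topology",
    "write_topology",
    "load_protein",
]


@dataclass
class PeakList:
    """A centroided spectrum: sorted m/z values, positive intensities.

    ``metadata`` carries acquisition context (ms_level, activation, power_W,
    time_ms, precursor_mz, precursor_z) as free-form keys.
    """

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size:
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if np.any(self.intensity <= 0):
                raise ValueError("intensities must be positive")
            if np.any(np.diff(self.mz) < 0):  # pragma: no cover - sorted above
                raise ValueError("m/z must be ascending")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def merged_with(self, other: "PeakList") -> "PeakList":
        """Combine two spectra (e.g. species mixtures) into one sorted list."""
        return PeakList(
            np.concatenate([self.mz, other.mz]),
            np.concatenate([self.intensity, other.intensity]),
            {**self.metadata, **other.metadata},
        )


def write_peaks(peaks: PeakList, tsv_path: str | Path, sidecar: bool = True) -> None:
    """Write a two-column TSV (m/z, intensity) plus a JSON metadata sidecar."""
    tsv_path = Path(tsv_path)
    with open(tsv_path, "w") as fh:
        fh.write("mz\tintensity\n")
        for m, i in zip(peaks.mz, peaks.intensity):
            fh.write(f"{m:.6f}\t{i:.6f}\n")
    if sidecar:
        meta = {k: _jsonable(v) for k, v in peaks.metadata.items()}
        tsv_path.with_suffix(tsv_path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1)
        )


def read_peaks(tsv_path: str | Path) -> PeakList:
    """Read a peak-list TSV; picks up a ``.meta.json`` sidecar if present."""
    tsv_path = Path(tsv_path)
    mzs: list[float] = []
    ints: list[float] = []
    with open(tsv_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                m = float(cols[0])
            except ValueError:
                continue  # header row
            mzs.append(m)
            ints.append(float(cols[1]))
    metadata: dict[str, Any] = {}
    sidecar = tsv_path.with_suffix(tsv_path.suffix + ".meta.json")
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
    return PeakList(np.array(mzs), np.array(ints), metadata)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences from FASTA, keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_topology(path: str | Path) -> dict[str, Any]:
    """Read a topology annotation JSON.

    Schema::

        {"segments": [{"start":.., "end":.., "kind":.., "helix_index":..}],
         "disulfides": [[i, j], ...],
         "oligomer_count": n,
         "helix_stability": {"1": 0.8, ...}}
    """
    return json.loads(Path(path).read_text())


def write_topology(spec: ProteinSpec, path: str | Path) -> None:
    doc = {
        "segments": [
            {
                "start": s.start,
                "end": s.end,
                "kind": s.kind,
                **({"helix_index": s.helix_index} if s.helix_index else {}),
            }
            for s in spec.topology
        ],
        "disulfides": [list(p) for p in spec.disulfides],
        "oligomer_count": spec.oligomer_count,
        "helix_stability": {str(k): v for k, v in spec.helix_stability.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_protein(
    fasta_path: str | Path,
    topology_path: str | Path | None = None,
    record_id: str | None = None,
) -> ProteinSpec:
    """Build a :class:`ProteinSpec` from a FASTA file and optional topology JSON."""
    seqs = read_fasta(fasta_path)
    if not seqs:
        raise ValueError(f"no sequences in {fasta_path}")
    if record_id is None:
        record_id, sequence = next(iter(seqs.items()))
    else:
        sequence = seqs[record_id]
    segments: list[Segment] = []
    disulfides: list[tuple[int, int]] = []
    oligomer = 1
    stability: dict[int, float] = {}
    if topology_path is not None:
        topo = read_topology(topology_path)
        segments = [
            Segment(
                start=int(s["start"]),
                end=int(s["end"]),
                kind=s["kind"],
                helix_index=s.get("helix_index"),
            )
            for s in topo.get("segments", [])
        ]
        disulfides = [tuple(p) for p in topo.get("disulfides", [])]
        oligomer = int(topo.get("oligomer_count", 1))
        stability = {int(k): float(v) for k, v in topo.get("helix_stability", {}).items()}
    return ProteinSpec(
        id=record_id,
        sequence=sequence,
        oligomer_count=oligomer,
        topology=segments,
        disulfides=disulfides,
        helix_stability=stability,
    )


def _jsonable(value: Any) -> Any:
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value
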