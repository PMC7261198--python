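"""File formats, configuration and provenance logging.

Sequences travel as FASTA (via Biopython); Calpha traces as multi-model PDB;
CV time series and deposited-kernel (HILLS-like) tables as whitespace files
with a ``#! FIELDS`` header line, the convention of common biased-MD
post-processing tools; run configuration as YAML key-value text.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sampling import GaussianKernel, MetaBias


class MalformedFileError(ValueError):
    """Raised with a line number when a text input cannot be parsed."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list:
    """Read NTD sequences from FASTA; record ids become subtype ids."""
    from .sequences import NTDSequence

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MalformedFileError(f"{path}: empty or not FASTA")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        try:
            out.append(NTDSequence(rec.id, seq))
        except ValueError as exc:
            raise MalformedFileError(f"{path}: record {rec.id}: {exc}") from exc
    return out


def write_fasta(path, seqs) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.subtype_id, description="")
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PDB (multi-model Calpha traces + charge pseudo-atoms)

def write_pdb(path, frames, sequence: str | None = None,
              charge_sites: list | None = None) -> None:
    """Write Calpha traces (nm -> Angstrom) as one MODEL per frame.

    ``frames`` is an iterable of (L, 3) arrays; optional per-frame charge
    pseudo-atom arrays are written as HETATM Q records.
    """
    lines = []
    for m, ca in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        serial = 1
        for i, (x, y, z) in enumerate(np.asarray(ca) * 10.0, start=1):
            resname = _three_letter(sequence[i - 1]) if sequence else "ALA"
            lines.append(
                f"ATOM  {serial:5d}  CA  {resname} A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        if charge_sites is not None:
            for j, (x, y, z) in enumerate(np.asarray(charge_sites[m - 1]) * 10.0, 1):
                lines.append(
                    f"HETATM{serial:5d}  Q   CHG B{j:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           X"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path) -> list[np.ndarray]:
    """Calpha traces (nm) per MODEL; single-model files give one frame."""
    frames: list[list[list[float]]] = []
    current: list[list[float]] | None = None
    saw_model = False
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        tag = line[:6].strip()
        if tag == "MODEL":
            saw_model = True
            current = []
        elif tag == "ENDMDL":
            if current is None:
                raise MalformedFileError(f"{path}:{ln}: ENDMDL without MODEL")
            frames.append(current)
            current = None
        elif tag == "ATOM":
            name = line[12:16].strip()
            if name != "CA":
                continue
            try:
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError as exc:
                raise MalformedFileError(f"{path}:{ln}: bad coordinates") from exc
            if current is None:
                current = []
            current.append(xyz)
    if current:
        frames.append(current)
    if not frames:
        raise MalformedFileError(f"{path}: no Calpha records found")
    if saw_model and current:
        raise MalformedFileError(f"{path}: unterminated MODEL block")
    return [np.array(f) / 10.0 for f in frames]


_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _three_letter(aa: str) -> str:
    return _THREE.get(aa, "UNK")


# ---------------------------------------------------------------------------
# FIELDS-header whitespace tables (COLVAR / HILLS dialects)

def write_timeseries(path, fields: list[str], columns: np.ndarray) -> None:
    """Whitespace table with a '#! FIELDS <names>' header line."""
    columns = np.atleast_2d(np.asarray(columns, dtype=float))
    if columns.shape[1] != len(fields):
        raise ValueError("column count must match field names")
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        # %.17g guarantees exact binary64 round trips (bias re-evaluation
        # from a written HILLS file must match the in-memory bias to 1e-9)
        for row in columns:
            fh.write(" ".join(f"{x: .17g}" for x in row) + "\n")


def read_timeseries(path) -> tuple[list[str], np.ndarray]:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise MalformedFileError(f"{path}:1: missing '#! FIELDS' header")
    fields = lines[0].split()[2:]
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != len(fields):
            raise MalformedFileError(
                f"{path}:{ln}: expected {len(fields)} fields, got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise MalformedFileError(f"{path}:{ln}: non-numeric value") from exc
    return fields, np.array(rows)


def write_hills(path, bias: MetaBias) -> None:
    """Serialize deposited kernels: time, centers, sigmas, height, biasf."""
    names = list(bias.cv_names)
    fields = (["time"] + names + [f"sigma_{n}" for n in names]
              + ["height", "biasf"])
    centers, sigmas, heights, times = bias.arrays()
    gamma = -1.0 if math.isinf(bias.bias_factor) else bias.bias_factor
    cols = np.column_stack([
        times, centers, sigmas, heights, np.full(len(heights), gamma)
    ]) if len(heights) else np.zeros((0, len(fields)))
    write_timeseries(path, fields, cols)


def read_hills(path) -> MetaBias:
    """Rebuild a MetaBias from a HILLS-like file (biasf -1 means infinity)."""
    fields, data = read_timeseries(path)
    if not fields or fields[0] != "time" or "height" not in fields:
        raise MalformedFileError(f"{path}: not a HILLS table")
    n_cv = (len(fields) - 3) // 2
    names = fields[1 : 1 + n_cv]
    if data.size == 0:
        return MetaBias(names)
    times = data[:, 0]
    if np.any(np.diff(times) < 0):
        raise MalformedFileError(f"{path}: kernel times not sorted")
    gamma = data[0, -1]
    kernels = [
        GaussianKernel(
            tuple(row[1 : 1 + n_cv]),
            tuple(row[1 + n_cv : 1 + 2 * n_cv]),
            row[1 + 2 * n_cv],
            int(row[0]),
        )
        for row in data
    ]
    return MetaBias.from_kernels(
        kernels, names, math.inf if gamma < 0 else float(gamma)
    )


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Round-trippable run configuration with mandatory seeds."""

    model: dict = field(default_factory=dict)
    sampling: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "runs"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise MalformedFileError(f"{path}: config must be a mapping")
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path, config: RunConfig | None, seed: int) -> None:
    """Provenance log: config hash, seed, package/library versions."""
    import h1ntd

    info = {
        "seed": seed,
        "config_hash": config.hash() if config else None,
        "h1ntd_version": getattr(h1ntd, "__version__", "unknown"),
        "numpy_version": np.__version__,
    }
    Path(path).write_text(json.dumps(info, indent=2) + "\n")
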