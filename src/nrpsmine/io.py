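"""Readers/writers for the formats the pipeline touches, plus run config."""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, fields
from io import StringIO
from pathlib import Path

import yaml
from Bio import SeqIO

from .fragments import Peak, PeakList

__all__ = ["FormatError", "RunConfig", "read_fasta", "write_fasta", "read_peaks", "write_matches_tsv"]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class RunConfig:
    """Run parameters; unknown keys in a config file are rejected."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    tol_ppm: float = 5.0
    tol_da: float = 0.01
    tol_rt: float = 0.05
    n_shuffles: int = 1000
    seed: int = 0
    reference_path: str | None = None
    code_table_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("tol_ppm", "tol_da", "tol_rt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """FASTA records as (id, uppercased sequence), in file order."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
            records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _read_peaks_csv(path: Path) -> PeakList:
    peaks = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and not _is_number(row[0]):
                continue  # header
            try:
                mz = float(row[0])
                intensity = float(row[1]) if len(row) > 1 and row[1] else 0.0
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric m/z or intensity: {row}") from None
            peaks.append(Peak(mz, intensity))
    return PeakList(peaks)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _read_peaks_mgf(path: Path) -> PeakList:
    from pyteomics import mgf

    with mgf.read(str(path)) as reader:
        try:
            spectrum = next(iter(reader))
        except StopIteration:
            raise FormatError(f"{path}: no spectra in MGF file") from None
    peaks = [
        Peak(float(mz), float(it))
        for mz, it in zip(spectrum["m/z array"], spectrum["intensity array"])
    ]
    parent = None
    pepmass = spectrum.get("params", {}).get("pepmass")
    if pepmass:
        parent = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
    return PeakList(peaks, parent_mz=parent)


def read_peaks(path: str | Path, fmt: str | None = None) -> PeakList:
    """Read a peak list from MGF or two-column CSV (mz,intensity)."""
    path = Path(path)
    if fmt is None:
        fmt = "mgf" if path.suffix.lower() == ".mgf" else "csv"
    if fmt == "csv":
        return _read_peaks_csv(path)
    if fmt == "mgf":
        return _read_peaks_mgf(path)
    raise ValueError(f"unknown peak-list format {fmt!r}")


def write_matches_tsv(match, path: str | Path | None = None) -> str:
    """Ladder-match assignments as TSV (peak_mz, series, index, calc_mz, ppm)."""
    buf = StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["peak_mz", "series", "index", "calc_mz", "ppm"])
    for peak, frag, err in match.assignments:
        w.writerow([f"{peak.mz:.4f}", frag.series, frag.index, f"{frag.mz:.4f}", f"{err:+.2f}"])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
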