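"""Peak-list containers and I/O (MGF, delimited tables, annotation reports).

MGF parsing and serialisation are delegated to :mod:`pyteomics.mgf`; a
structural pre-validation pass supplies the line-number diagnostics the
pyteomics reader does not (unbalanced BEGIN/END IONS blocks, non-numeric peak
lines, missing PEPMASS) and normalises peak lines that omit an intensity
token to intensity 1.0, which pyteomics would otherwise silently misalign.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from pyteomics import mgf as _mgf

from .exceptions import DomainError, ParseError, SchemaError

logger = logging.getLogger(__name__)


class Peak(NamedTuple):
    mz: float
    intensity: float = 1.0


def _prepare_peaks(peaks: Iterable[Peak | tuple[float, float]]) -> tuple[Peak, ...]:
    """Validate, sort ascending and merge exact duplicate m/z by intensity sum."""
    merged: dict[float, float] = {}
    n_dup = 0
    for p in peaks:
        mz, intensity = float(p[0]), float(p[1])
        if not mz > 0:
            raise DomainError(f"peak m/z must be positive, got {mz}")
        if intensity < 0:
            raise DomainError(f"peak intensity must be non-negative, got {intensity}")
        if mz in merged:
            n_dup += 1
        merged[mz] = merged.get(mz, 0.0) + intensity
    if n_dup:
        logger.info("merged %d duplicate m/z value(s) by intensity sum", n_dup)
    return tuple(Peak(mz, merged[mz]) for mz in sorted(merged))


@dataclass(frozen=True)
class Spectrum:
    """A centroided peak list, sorted strictly ascending in m/z.

    ``ms_level`` 2 requires ``precursor_mz``; duplicate m/z values are merged
    (intensity-summed) at construction so downstream graph algorithms can
    assume strict ordering.
    """

    peaks: tuple[Peak, ...]
    ms_level: int = 1
    precursor_mz: float | None = None
    retention_time: float | None = None  # minutes
    source_id: str = ""
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", _prepare_peaks(self.peaks))
        if self.ms_level not in (1, 2):
            raise DomainError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise DomainError("an MS2 spectrum requires precursor_mz")

    @property
    def mzs(self) -> tuple[float, ...]:
        return tuple(p.mz for p in self.peaks)

    @property
    def intensities(self) -> tuple[float, ...]:
        return tuple(p.intensity for p in self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def closest_peak(self, mz: float) -> Peak | None:
        if not self.peaks:
            return None
        return min(self.peaks, key=lambda p: (abs(p.mz - mz), p.mz))


@dataclass
class SpectrumSet:
    """An ordered collection of spectra with run-level metadata."""

    spectra: list[Spectrum] = field(default_factory=list)
    run_metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.source_id for s in self.spectra if s.source_id]
        if len(ids) != len(set(ids)):
            raise DomainError("source_id values must be unique within a SpectrumSet")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def ms1(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

_KNOWN_HEADERS = {"TITLE", "PEPMASS", "RTINSECONDS", "MSLEVEL", "CHARGE"}


def _validate_and_normalize_mgf(lines: Iterable[str]) -> str:
    """Structural check with line numbers; returns a normalised MGF text.

    Peak lines missing the intensity token get intensity 1.0 appended.
    """
    out: list[str] = []
    in_block = False
    block_start = 0
    has_pepmass = False
    ms_level = 2
    last = 0
    for lineno, raw in enumerate(lines, start=1):
        last = lineno
        line = raw.rstrip("\n")
        stripped = line.strip()
        if stripped == "BEGIN IONS":
            if in_block:
                raise ParseError("BEGIN IONS inside an open block", lineno)
            in_block, block_start, has_pepmass, ms_level = True, lineno, False, 2
        elif stripped == "END IONS":
            if not in_block:
                raise ParseError("END IONS without matching BEGIN IONS", lineno)
            if ms_level == 2 and not has_pepmass:
                raise ParseError(
                    f"MS2 block starting at line {block_start} has no PEPMASS", lineno
                )
            in_block = False
        elif in_block and stripped and "=" in stripped and not stripped[0].isdigit():
            key = stripped.split("=", 1)[0].strip().upper()
            if key == "PEPMASS":
                has_pepmass = True
            elif key == "MSLEVEL":
                try:
                    ms_level = int(stripped.split("=", 1)[1].strip())
                except ValueError:
                    raise ParseError("non-integer MSLEVEL", lineno) from None
        elif in_block and stripped:
            tokens = stripped.split()
            try:
                [float(t) for t in tokens[:2]]
            except ValueError:
                raise ParseError(f"non-numeric peak line {stripped!r}", lineno) from None
            if len(tokens) == 1:
                line = f"{stripped} 1.0"
        out.append(line)
    if in_block:
        raise ParseError(f"block starting at line {block_start} missing END IONS", last)
    return "\n".join(out) + "\n"


def read_mgf(path: str | Path) -> SpectrumSet:
    """Read a Mascot generic format file into a :class:`SpectrumSet`.

    Interpreted headers: PEPMASS (first token -> precursor m/z), RTINSECONDS
    (-> minutes), TITLE (-> source_id), MSLEVEL (default 2). Unknown headers
    are preserved in ``Spectrum.metadata``.
    """
    path = Path(path)
    with open(path) as fh:
        text = _validate_and_normalize_mgf(fh)
    spectra: list[Spectrum] = []
    with _mgf.read(io.StringIO(text), use_index=False) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            ms_level = int(params.get("mslevel", 2))
            pepmass = params.get("pepmass")
            precursor = float(pepmass[0]) if pepmass else None
            rt = params.get("rtinseconds")
            metadata = {
                k: str(v)
                for k, v in params.items()
                if k.upper() not in _KNOWN_HEADERS
            }
            spectra.append(
                Spectrum(
                    peaks=tuple(
                        Peak(float(mz), float(it))
                        for mz, it in zip(entry["m/z array"], entry["intensity array"])
                    ),
                    ms_level=ms_level,
                    precursor_mz=precursor,
                    retention_time=float(rt) / 60.0 if rt is not None else None,
                    source_id=str(params.get("title", f"scan_{i}")),
                    metadata=metadata,
                )
            )
    return SpectrumSet(spectra=spectra, run_metadata={"source": str(path)})


def write_mgf(spectra: SpectrumSet | Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (via pyteomics); MS1 spectra carry MSLEVEL=1."""
    items = list(spectra)
    records = []
    for i, s in enumerate(items):
        params: dict[str, object] = {"title": s.source_id or f"scan_{i}"}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        if s.retention_time is not None:
            params["rtinseconds"] = round(s.retention_time * 60.0, 6)
        if s.ms_level != 2:
            params["mslevel"] = s.ms_level
        params.update(s.metadata)
        records.append(
            {
                "m/z array": list(s.mzs),
                "intensity array": list(s.intensities),
                "params": params,
            }
        )
    with open(path, "w") as fh:
        _mgf.write(records, fh)


# ---------------------------------------------------------------------------
# Delimited peak tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableDialect:
    """How to read a delimited peak table: separator and column mapping."""

    delimiter: str = "\t"
    mz_column: str = "mz"
    intensity_column: str | None = "intensity"
    ms_level: int = 1
    precursor_mz: float | None = None


def read_peak_table(path: str | Path, dialect: TableDialect = TableDialect()) -> Spectrum:
    """Read a single delimited peak table into one :class:`Spectrum`."""
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter)
    if dialect.mz_column not in df.columns:
        raise SchemaError(
            f"{path}: missing mandated column {dialect.mz_column!r} "
            f"(found {list(df.columns)})"
        )
    if df.empty:
        logger.warning("%s: header-only peak table, returning empty spectrum", path)
        peaks: list[Peak] = []
    else:
        mzs = pd.to_numeric(df[dialect.mz_column], errors="coerce")
        if mzs.isna().any():
            raise ParseError(f"{path}: non-numeric m/z value in column {dialect.mz_column!r}")
        if (mzs <= 0).any():
            bad = df.index[mzs <= 0][0]
            raise ParseError(f"{path}: non-positive m/z in data row {bad}")
        if dialect.intensity_column and dialect.intensity_column in df.columns:
            intens = pd.to_numeric(df[dialect.intensity_column], errors="coerce").fillna(1.0)
        else:
            intens = pd.Series(1.0, index=df.index)
        peaks = [Peak(m, i) for m, i in zip(mzs, intens)]
    return Spectrum(
        peaks=tuple(peaks),
        ms_level=dialect.ms_level,
        precursor_mz=dialect.precursor_mz,
        source_id=path.stem,
    )


# ---------------------------------------------------------------------------
# Annotation reports
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "precursor_mz",
    "rt",
    "family",
    "chain_length",
    "sequence",
    "score",
    "mass_error",
]


def _sequence_string(position_sets: Sequence[Sequence[str]]) -> str:
    parts = []
    for cands in position_sets:
        cands = list(cands)
        if not cands:
            parts.append("?")
        elif len(cands) == 1:
            parts.append(cands[0])
        else:
            parts.append("[" + "|".join(cands) + "]")
    return "-".join(parts)


def write_annotation_report(annotations, path: str | Path, format: str = "tabular") -> None:
    """Write annotations as a TSV summary or a structured JSON document.

    Tabular: one row per annotated precursor (precursor_mz, rt, family,
    chain_length, sequence with ambiguity sets in brackets, score,
    mass_error). Structured: full ladders and per-step errors, round-trippable
    via :func:`read_annotation_report`.
    """
    path = Path(path)
    if format == "tabular":
        rows = []
        for a in annotations:
            rows.append(
                {
                    "precursor_mz": a.precursor_mz,
                    "rt": a.retention_time,
                    "family": a.family,
                    "chain_length": a.chain_length,
                    "sequence": _sequence_string(a.sequence),
                    "score": round(a.score, 4),
                    "mass_error": a.lipid_error,
                }
            )
        pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "structured":
        payload = [a.to_dict() for a in annotations]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, allow_nan=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_annotation_report(path: str | Path) -> list[dict]:
    """Read back a structured (JSON) annotation report."""
    with open(path) as fh:
        return json.load(fh)
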