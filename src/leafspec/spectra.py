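"""Spectrum and sample data model, plain-text I/O, and calibration.

A :class:`Spectrum` is a wavelength-indexed intensity curve with a declared
kind (``radiance``, ``reflectance`` or ``fluorescence``).  A
:class:`SampleRecord` bundles the replicate spectra of one leaf sample with
its nitrogen label and treatment metadata.  Spectrum files are two-column
delimited text (``wavelength_nm,value``); manifests are delimited tables
listing replicate files per sample.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    CalibrationError,
    ManifestError,
    SpectrumFormatError,
    SpectrumParseError,
)

logger = logging.getLogger(__name__)

KINDS = ("radiance", "reflectance", "fluorescence")

#: Reflectance values above this are rejected; values in (1, 1.5] are kept
#: with a warning (near-99% reference panels can yield ratios slightly > 1).
REFLECTANCE_MAX = 1.5


@dataclass
class Spectrum:
    """A sampled intensity curve on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KINDS:
            raise SpectrumFormatError(f"unknown spectrum kind {self.kind!r}")
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise SpectrumFormatError("wavelengths and values must be 1-D")
        if len(self.wavelengths) != len(self.values):
            raise SpectrumFormatError(
                f"length mismatch: {len(self.wavelengths)} wavelengths vs "
                f"{len(self.values)} values"
            )
        if len(self.wavelengths) < 2:
            raise SpectrumFormatError("a spectrum needs at least 2 channels")
        dl = np.diff(self.wavelengths)
        if np.any(dl == 0):
            dup = self.wavelengths[:-1][dl == 0][0]
            raise SpectrumFormatError(f"duplicate wavelength {dup} nm")
        if np.any(dl < 0):
            raise SpectrumFormatError("wavelengths must be strictly increasing")
        if self.kind == "reflectance":
            if np.any(self.values < 0) or np.any(self.values > REFLECTANCE_MAX):
                raise SpectrumFormatError(
                    "reflectance values outside [0, %.1f]" % REFLECTANCE_MAX
                )
            if np.any(self.values > 1.0):
                logger.warning(
                    "reflectance exceeds 1.0 at %d channel(s); kept unclipped",
                    int(np.sum(self.values > 1.0)),
                )
        else:
            if np.any(self.values < 0):
                raise SpectrumFormatError(f"{self.kind} values must be >= 0")

    def __len__(self) -> int:
        return len(self.wavelengths)

    def with_values(self, values: np.ndarray, **meta) -> "Spectrum":
        """Copy of this spectrum with new values (same grid/kind)."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Spectrum(self.wavelengths.copy(), np.asarray(values, float),
                        self.kind, new_meta)

    def same_grid(self, other: "Spectrum", atol: float = 1e-9) -> bool:
        return len(self) == len(other) and bool(
            np.allclose(self.wavelengths, other.wavelengths, atol=atol)
        )


@dataclass
class SampleRecord:
    """One leaf sample: replicate spectra of both modalities plus label."""

    sample_id: str
    year: int
    n_rate: float
    lnc: float | None
    reflectance_reps: list[Spectrum] = field(default_factory=list)
    fluorescence_reps: list[Spectrum] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rate < 0:
            raise ManifestError(f"{self.sample_id}: n_rate must be >= 0")
        if self.lnc is not None and not self.lnc > 0:
            raise ManifestError(f"{self.sample_id}: lnc must be > 0 when present")
        _check_shared_grid(self.reflectance_reps, self.sample_id, "reflectance")
        _check_shared_grid(self.fluorescence_reps, self.sample_id, "fluorescence")

    @property
    def has_label(self) -> bool:
        return self.lnc is not None


def _check_shared_grid(reps: Sequence[Spectrum], sid: str, modality: str) -> None:
    for r in reps[1:]:
        if not reps[0].same_grid(r):
            raise AlignmentError(
                f"{sid}: {modality} replicates are on different wavelength grids"
            )


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_spectrum(path: str | Path, kind: str) -> Spectrum:
    """Read a two-column delimited text spectrum file.

    The header row is required; rows may appear in any wavelength order and
    are sorted ascending.  Duplicate wavelengths are rejected.
    """
    path = Path(path)
    with open(path, "r", newline="") as fh:
        header = fh.readline()
        if not header.strip():
            raise SpectrumParseError(f"{path}: empty file")
        delim = _sniff_delimiter(header)
        wl: list[float] = []
        vals: list[float] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.strip().split(delim)
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                wl.append(float(parts[0]))
                vals.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric row {line.strip()!r}"
                ) from exc
    order = np.argsort(np.asarray(wl), kind="stable")
    wl_arr = np.asarray(wl, float)[order]
    val_arr = np.asarray(vals, float)[order]
    if np.any(np.diff(wl_arr) == 0):
        dup = wl_arr[:-1][np.diff(wl_arr) == 0][0]
        raise SpectrumFormatError(f"{path}: duplicate wavelength {dup} nm")
    return Spectrum(wl_arr, val_arr, kind, {"source": str(path)})


def write_spectrum(s: Spectrum, path: str | Path, fmt: str = "%.6f") -> None:
    """Write a spectrum as ``wavelength_nm,value`` delimited text."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("wavelength_nm,value\n")
        for w, v in zip(s.wavelengths, s.values):
            fh.write(("%s," + fmt + "\n") % (_fmt_wavelength(w), v))


def _fmt_wavelength(w: float) -> str:
    return "%g" % w


MANIFEST_COLUMNS = (
    "sample_id",
    "year",
    "n_rate_kg_ha",
    "lnc_percent",
    "reflectance_files",
    "fluorescence_files",
)


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Load a sample manifest and every spectrum file it references.

    Replicate paths are ``;``-separated and resolved relative to the
    manifest's directory.  An empty ``lnc_percent`` cell yields an unlabeled
    record (``lnc is None``).
    """
    path = Path(path)
    base = path.parent
    records: list[SampleRecord] = []
    with open(path, "r", newline="") as fh:
        delim = _sniff_delimiter(fh.readline())
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ManifestError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            sid = row["sample_id"].strip()
            lnc_cell = (row["lnc_percent"] or "").strip()
            lnc = float(lnc_cell) if lnc_cell else None
            refl = _load_reps(row["reflectance_files"], base, "reflectance", sid)
            fluo = _load_reps(row["fluorescence_files"], base, "fluorescence", sid)
            records.append(
                SampleRecord(
                    sample_id=sid,
                    year=int(row["year"]),
                    n_rate=float(row["n_rate_kg_ha"]),
                    lnc=lnc,
                    reflectance_reps=refl,
                    fluorescence_reps=fluo,
                )
            )
    return records


def _load_reps(cell: str, base: Path, kind: str, sid: str) -> list[Spectrum]:
    reps = []
    for rel in (cell or "").split(";"):
        rel = rel.strip()
        if not rel:
            continue
        p = base / rel
        if not p.exists():
            raise ManifestError(f"sample {sid}: spectrum file not found: {p}")
        reps.append(read_spectrum(p, kind))
    return reps


def write_manifest(records: Iterable[SampleRecord], path: str | Path,
                   spectra_dir: str = "spectra") -> None:
    """Write records and their spectra to ``path`` + a spectra directory."""
    path = Path(path)
    outdir = path.parent / spectra_dir
    outdir.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for rec in records:
            refl_files, fluo_files = [], []
            for i, s in enumerate(rec.reflectance_reps):
                name = f"{rec.sample_id}_refl_{i}.csv"
                write_spectrum(s, outdir / name)
                refl_files.append(f"{spectra_dir}/{name}")
            for i, s in enumerate(rec.fluorescence_reps):
                name = f"{rec.sample_id}_fluo_{i}.csv"
                write_spectrum(s, outdir / name)
                fluo_files.append(f"{spectra_dir}/{name}")
            writer.writerow([
                rec.sample_id,
                rec.year,
                "%g" % rec.n_rate,
                "" if rec.lnc is None else "%.6f" % rec.lnc,
                ";".join(refl_files),
                ";".join(fluo_files),
            ])


def compute_reflectance(leaf: Spectrum, reference: Spectrum) -> Spectrum:
    """Ratio-calibrate leaf radiance against a reference-panel radiance.

    The reflectance at each wavelength is leaf(λ) / reference(λ).  Both
    spectra must share one grid and the reference must be positive
    everywhere.
    """
    if leaf.kind != "radiance" or reference.kind != "radiance":
        raise CalibrationError("both inputs must be radiance spectra")
    if not leaf.same_grid(reference):
        raise AlignmentError("leaf and reference are on different grids")
    bad = reference.values <= 0
    if np.any(bad):
        lam = reference.wavelengths[bad][0]
        raise CalibrationError(f"reference radiance <= 0 at {lam} nm")
    ratio = leaf.values / reference.values
    if np.any(ratio > REFLECTANCE_MAX):
        lam = leaf.wavelengths[ratio > REFLECTANCE_MAX][0]
        raise CalibrationError(
            f"reflectance ratio {ratio.max():.3f} > {REFLECTANCE_MAX} at {lam} nm"
        )
    return Spectrum(leaf.wavelengths.copy(), ratio, "reflectance",
                    {"calibration": "reference_ratio"})


def average_replicates(reps: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate spectra on one shared grid."""
    if len(reps) == 0:
        raise ValueError("average_replicates needs at least one replicate")
    first = reps[0]
    for r in reps[1:]:
        if r.kind != first.kind:
            raise AlignmentError("replicates mix spectrum kinds")
        if not first.same_grid(r):
            raise AlignmentError("replicates are on different wavelength grids")
    mean = np.mean([r.values for r in reps], axis=0)
    return Spectrum(first.wavelengths.copy(), mean, first.kind,
                    {"n_replicates": len(reps)})
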