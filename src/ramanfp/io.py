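"""Reading, writing and validation of spectra and cohort metadata.

Spectra travel as two-column plain text (Raman shift in cm^-1,
intensity in arbitrary units), whitespace- or comma-delimited, with
optional ``#`` comment lines — the least common denominator of
spectrometer exports.  Cohorts combine per-subject metadata (group,
demographics, clinical scores) with one or more acquisitions per
subject.  The shift axis is stored strictly ascending everywhere; all
downstream modules rely on that convention.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("CTRL", "PD", "AD")


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed."""


class ValidationError(ValueError):
    """A record or dataset violates an invariant."""


@dataclass(frozen=True)
class RamanSpectrum:
    """One Raman acquisition: shift axis (cm^-1) plus intensities (a.u.)."""

    shift_axis: np.ndarray
    intensities: np.ndarray
    subject_id: str = ""
    acquisition_id: str = ""

    def __post_init__(self):
        axis = np.asarray(self.shift_axis, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if axis.ndim != 1 or inten.ndim != 1:
            raise ValidationError("axis and intensities must be 1-D")
        if axis.size != inten.size:
            raise ValidationError(
                f"axis length {axis.size} != intensities length {inten.size}")
        if not (np.all(np.isfinite(axis)) and np.all(np.isfinite(inten))):
            raise ValidationError("spectrum contains non-finite values")
        if axis.size >= 2 and not np.all(np.diff(axis) > 0):
            raise ValidationError("shift axis must be strictly increasing")
        object.__setattr__(self, "shift_axis", axis)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return self.shift_axis.size

    def with_intensities(self, intensities: np.ndarray) -> "RamanSpectrum":
        return replace(self, intensities=np.asarray(intensities, dtype=float))

    def with_axis(self, axis: np.ndarray, intensities: np.ndarray) -> "RamanSpectrum":
        return replace(self, shift_axis=np.asarray(axis, dtype=float),
                       intensities=np.asarray(intensities, dtype=float))


@dataclass(frozen=True)
class SubjectRecord:
    """Group label, demographics and (for PD) clinical scores.

    ``updrs3`` (motor UPDRS part III), ``hy`` (Hoehn & Yahr stage) and
    ``ledd`` (levodopa equivalent daily dose, mg/day) are defined for
    PD subjects only and are ``None`` otherwise.
    """

    subject_id: str
    group: str
    age: float
    sex: str
    updrs3: float | None = None
    hy: float | None = None
    ledd: float | None = None

    def __post_init__(self):
        if self.group not in VALID_GROUPS:
            raise ValidationError(
                f"subject {self.subject_id!r}: group {self.group!r} not in "
                f"{VALID_GROUPS}")
        if not self.age > 0:
            raise ValidationError(f"subject {self.subject_id!r}: age must be > 0")
        if self.sex not in ("M", "F"):
            raise ValidationError(
                f"subject {self.subject_id!r}: sex {self.sex!r} not in ('M','F')")
        if self.group != "PD":
            for name in ("updrs3", "hy", "ledd"):
                if getattr(self, name) is not None:
                    raise ValidationError(
                        f"subject {self.subject_id!r}: {name} given for "
                        f"non-PD group {self.group}")


@dataclass
class CohortDataset:
    """Validated bundle of subjects and their spectra.

    Every spectrum's ``subject_id`` resolves to a subject; subjects may
    have zero spectra (retained with a warning — they drop out of any
    per-spectrum analysis downstream).
    """

    subjects: dict[str, SubjectRecord] = field(default_factory=dict)
    spectra: list[RamanSpectrum] = field(default_factory=list)

    def group_of(self, subject_id: str) -> str:
        return self.subjects[subject_id].group

    def spectra_of(self, subject_id: str) -> list[RamanSpectrum]:
        return [s for s in self.spectra if s.subject_id == subject_id]

    def subject_ids(self) -> list[str]:
        return sorted(self.subjects)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {sid: 0 for sid in self.subjects}
        for s in self.spectra:
            out[s.subject_id] += 1
        return out

    def labels(self) -> np.ndarray:
        """Group label per spectrum, in spectra order."""
        return np.array([self.group_of(s.subject_id) for s in self.spectra])

    def intensity_matrix(self) -> np.ndarray:
        """Spectra stacked row-wise; requires a common grid."""
        if not self.spectra:
            raise ValidationError("dataset has no spectra")
        grid = self.spectra[0].shift_axis
        for s in self.spectra[1:]:
            if s.shift_axis.size != grid.size or not np.allclose(s.shift_axis, grid):
                raise ValidationError("spectra are not on a common grid")
        return np.vstack([s.intensities for s in self.spectra])

    @property
    def grid(self) -> np.ndarray:
        return self.spectra[0].shift_axis

    def replace_spectra(self, spectra: list[RamanSpectrum]) -> "CohortDataset":
        return CohortDataset(subjects=dict(self.subjects), spectra=list(spectra))


def read_spectrum_file(path, subject_id: str = "",
                       acquisition_id: str = "") -> RamanSpectrum:
    """Parse a two-column text spectrum (whitespace- or comma-delimited).

    Lines starting with ``#`` and blank lines are skipped.  A descending
    axis (as exported by some instruments) is sorted ascending.
    """
    shifts: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected two columns, got {line!r}")
            try:
                shifts.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric value in {line!r}") from exc
    if len(shifts) < 3:
        raise SpectrumParseError(
            f"{path}: malformed spectrum with {len(shifts)} points (< 3)")
    axis = np.asarray(shifts)
    inten = np.asarray(values)
    order = np.argsort(axis, kind="stable")
    return RamanSpectrum(axis[order], inten[order],
                         subject_id=subject_id, acquisition_id=acquisition_id)


def write_spectrum_file(spectrum: RamanSpectrum, path) -> None:
    """Write a spectrum as two-column text at full double precision."""
    with open(path, "w") as fh:
        fh.write(f"# subject_id={spectrum.subject_id} "
                 f"acquisition_id={spectrum.acquisition_id}\n")
        fh.write("# shift_cm-1 intensity_au\n")
        for x, y in zip(spectrum.shift_axis, spectrum.intensities):
            fh.write(f"{float(x)!r} {float(y)!r}\n")


def _parse_optional(value: str) -> float | None:
    value = (value or "").strip()
    return None if value == "" else float(value)


def read_metadata_table(path) -> dict[str, SubjectRecord]:
    """Read a subject metadata CSV keyed by subject_id.

    Required columns: subject_id, group, age, sex.  Optional columns
    updrs3, hy, ledd apply to PD subjects.
    """
    out: dict[str, SubjectRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"subject_id", "group", "age", "sex"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            sid = row["subject_id"].strip()
            if sid in out:
                raise ValidationError(f"{path}: duplicate subject_id {sid!r}")
            out[sid] = SubjectRecord(
                subject_id=sid,
                group=row["group"].strip(),
                age=float(row["age"]),
                sex=row["sex"].strip(),
                updrs3=_parse_optional(row.get("updrs3", "")),
                hy=_parse_optional(row.get("hy", "")),
                ledd=_parse_optional(row.get("ledd", "")),
            )
    return out


def write_metadata_table(subjects: dict[str, SubjectRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group", "age", "sex", "updrs3", "hy", "ledd"])
        for sid in sorted(subjects):
            rec = subjects[sid]
            writer.writerow([
                rec.subject_id, rec.group, rec.age, rec.sex,
                "" if rec.updrs3 is None else rec.updrs3,
                "" if rec.hy is None else rec.hy,
                "" if rec.ledd is None else rec.ledd,
            ])


def assemble_cohort(spectra, subjects) -> CohortDataset:
    """Bundle spectra and subjects into a validated dataset.

    Spectra referencing unknown subjects raise; subjects with zero
    spectra are retained with a warning.  The result is independent of
    input order (spectra are sorted by subject then acquisition id).
    """
    subjects = dict(subjects)
    spectra = sorted(spectra, key=lambda s: (s.subject_id, s.acquisition_id))
    orphans = sorted({s.subject_id for s in spectra} - set(subjects))
    if orphans:
        raise ValidationError(f"spectra reference unknown subjects: {orphans}")
    ds = CohortDataset(subjects=subjects, spectra=spectra)
    for sid, n in sorted(ds.counts().items()):
        logger.info("subject %s: %d spectra", sid, n)
        if n == 0:
            logger.warning("subject %s has no spectra; retained but will "
                           "drop out of per-spectrum analyses", sid)
    return ds


def read_wide_matrix(path) -> list[RamanSpectrum]:
    """Read a wide-matrix CSV: columns subject_id, acquisition_id, then
    one column per grid wavenumber."""
    df = pd.read_csv(path, float_precision="round_trip")
    grid = np.array([float(c) for c in df.columns[2:]])
    out = []
    for _, row in df.iterrows():
        out.append(RamanSpectrum(grid, row.iloc[2:].to_numpy(dtype=float),
                                 subject_id=str(row.iloc[0]),
                                 acquisition_id=str(row.iloc[1])))
    return out


def write_wide_matrix(spectra: list[RamanSpectrum], path) -> None:
    """Write spectra sharing a common grid as a wide-matrix CSV."""
    if not spectra:
        raise ValidationError("no spectra to write")
    grid = spectra[0].shift_axis
    for s in spectra:
        if not np.array_equal(s.shift_axis, grid):
            raise ValidationError("spectra are not on a common grid")
    df = pd.DataFrame(np.vstack([s.intensities for s in spectra]),
                      columns=[repr(float(x)) for x in grid])
    df.insert(0, "acquisition_id", [s.acquisition_id for s in spectra])
    df.insert(0, "subject_id", [s.subject_id for s in spectra])
    df.to_csv(path, index=False, float_format="%.17g")
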