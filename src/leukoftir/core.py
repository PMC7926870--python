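"""Domain types and file I/O for serum mid-infrared spectra.

A :class:`Spectrum` is one absorbance trace on a strictly increasing
wavenumber grid (cm⁻¹) together with sample metadata; a
:class:`CohortSet` is a labelled collection of spectra supporting
replicate and group averaging.  Spectra travel as two-column CSV or
JCAMP-DX files, cohorts as a manifest CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("control", "bcp_all", "unknown")

__all__ = [
    "GROUPS",
    "Spectrum",
    "CohortSet",
    "SpectrumFormatError",
    "ValidationError",
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "load_cohort",
    "write_cohort",
    "average_replicates",
]


class SpectrumFormatError(ValueError):
    """A spectrum file could not be parsed."""


class ValidationError(ValueError):
    """Domain invariant violated (grids, labels, duplicate replicates...)."""


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace A(k) with sample metadata.

    Parameters
    ----------
    sample_id : str
        Subject identifier; replicates of the same subject share it.
    group : str
        One of ``control``, ``bcp_all``, ``unknown``.
    replicate : int
        1-based replicate index.
    wavenumbers : ndarray
        Strictly increasing grid in cm⁻¹.
    absorbance : ndarray
        Absorbance in arbitrary units, same length as the grid.
    meta : dict
        Optional clinical metadata; recognised keys are ``wbc`` and
        ``blasts`` (both 10³/µL).
    """

    sample_id: str
    group: str = "unknown"
    replicate: int = 1
    wavenumbers: np.ndarray = field(default_factory=lambda: np.array([]))
    absorbance: np.ndarray = field(default_factory=lambda: np.array([]))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavenumbers", k)
        object.__setattr__(self, "absorbance", a)
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.replicate < 1:
            raise ValidationError("replicate index must be >= 1")
        if k.ndim != 1 or a.ndim != 1 or k.size != a.size:
            raise ValidationError("wavenumbers and absorbance must be 1-D and equal length")
        if k.size < 3:
            raise ValidationError("spectrum needs at least 3 points")
        if not np.all(np.isfinite(k)) or not np.all(np.isfinite(a)):
            raise ValidationError("non-finite values in spectrum")
        if np.any(k <= 0):
            raise ValidationError("wavenumbers must be positive")
        if np.any(np.diff(k) <= 0):
            raise ValidationError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def with_absorbance(self, a: np.ndarray, **meta_updates) -> "Spectrum":
        """Copy of this spectrum with a new absorbance vector."""
        return replace(self, absorbance=np.asarray(a, dtype=float))

    def with_grid(self, k: np.ndarray, a: np.ndarray) -> "Spectrum":
        return replace(
            self,
            wavenumbers=np.asarray(k, dtype=float),
            absorbance=np.asarray(a, dtype=float),
        )


@dataclass
class CohortSet:
    """Collection of spectra with group labels and clinical counts."""

    spectra: list[Spectrum]
    grid: np.ndarray | None = None  # common wavenumber grid, set by resampling

    def __post_init__(self) -> None:
        seen = set()
        for s in self.spectra:
            key = (s.sample_id, s.replicate)
            if key in seen:
                raise ValidationError(f"duplicate (sample_id, replicate) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for s in self.spectra:
            if s.sample_id not in out:
                out.append(s.sample_id)
        return out

    def subset(self, group: str) -> "CohortSet":
        return CohortSet([s for s in self.spectra if s.group == group], grid=self.grid)

    def labels(self) -> pd.Series:
        """Group label per unique sample_id, in first-appearance order."""
        d: dict[str, str] = {}
        for s in self.spectra:
            d.setdefault(s.sample_id, s.group)
        return pd.Series(d, name="group")

    def counts(self) -> pd.DataFrame:
        """WBC / blast table per unique sample_id (NaN where absent)."""
        rows = {}
        for s in self.spectra:
            rows.setdefault(
                s.sample_id,
                {
                    "group": s.group,
                    "wbc": s.meta.get("wbc", np.nan),
                    "blasts": s.meta.get("blasts", np.nan),
                },
            )
        return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# spectrum files


def _read_csv_spectrum(path: Path) -> tuple[np.ndarray, np.ndarray]:
    ks: list[float] = []
    As: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p for p in line.replace(";", ",").split(",") if p.strip()]
            if len(parts) != 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                ks.append(float(parts[0]))
                As.append(float(parts[1]))
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise SpectrumFormatError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
    return np.array(ks), np.array(As)


def _read_jcamp_spectrum(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader: AFFN ``XYDATA=(X++(Y..Y))`` and ``XYPOINTS``.

    Compressed (SQZ/DIF/DUP) ordinates are not supported.  FIRSTX/LASTX/
    NPOINTS, when present, define the XYDATA abscissa spacing; otherwise it
    is inferred from consecutive line starts.
    """
    lines = Path(path).read_text().splitlines()
    headers: dict[str, str] = {}
    mode = None
    xydata: list[tuple[float, list[float]]] = []  # (line start x, y values)
    xypts: list[tuple[float, float]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("$$")[0].strip()
        if not line:
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.replace(" ", "").replace("-", "").upper()
            headers[label] = value.strip()
            if label == "XYDATA":
                mode = "xydata"
            elif label == "XYPOINTS":
                mode = "xypoints"
            elif label in {"END", "ENDXYDATA"}:
                mode = None
            continue
        if mode is None:
            continue
        try:
            if mode == "xydata":
                vals = [float(v) for v in line.replace(",", " ").split()]
                if len(vals) < 2:
                    raise ValueError
                xydata.append((vals[0], vals[1:]))
            else:
                for pair in line.split(";"):
                    pv = pair.replace(",", " ").split()
                    if not pv:
                        continue
                    if len(pv) != 2:
                        raise ValueError
                    xypts.append((float(pv[0]), float(pv[1])))
        except ValueError:
            raise SpectrumFormatError(
                f"{path}:{lineno}: unparsable data line {line!r}"
            ) from None
    xfactor = float(headers.get("XFACTOR", 1.0))
    yfactor = float(headers.get("YFACTOR", 1.0))
    if xydata:
        npts = sum(len(yv) for _, yv in xydata)
        if {"FIRSTX", "LASTX"} <= headers.keys() and npts > 1:
            dx = (float(headers["LASTX"]) - float(headers["FIRSTX"])) / (npts - 1)
            dx /= xfactor
        else:  # infer spacing from consecutive line starts
            dx = None
            for (x0, yv), (x1, _) in zip(xydata, xydata[1:]):
                if yv:
                    dx = (x1 - x0) / len(yv)
                    break
            if dx is None:
                raise SpectrumFormatError(f"{path}: cannot infer XYDATA spacing")
        xs = [x0 + j * dx for x0, yv in xydata for j in range(len(yv))]
        ys = [y for _, yv in xydata for y in yv]
    elif xypts:
        xs, ys = (list(v) for v in zip(*xypts))
    else:
        raise SpectrumFormatError(f"{path}: no XYDATA/XYPOINTS block found")
    return np.array(xs) * xfactor, np.array(ys) * yfactor


def read_spectrum(
    path: str | Path,
    format: str | None = None,
    sample_id: str | None = None,
) -> Spectrum:
    """Read a spectrum file (two-column CSV or JCAMP-DX).

    Descending-wavenumber files (a common IR dialect) are sorted
    ascending.  Duplicate wavenumbers raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in {".jdx", ".dx", ".jcm"} else "csv"
    if format == "csv":
        k, a = _read_csv_spectrum(path)
    elif format == "jcamp":
        k, a = _read_jcamp_spectrum(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    order = np.argsort(k, kind="stable")
    k, a = k[order], a[order]
    if np.any(np.diff(k) <= 0):
        raise ValidationError(f"{path}: duplicate wavenumbers after sorting")
    return Spectrum(sample_id=sample_id or path.stem, wavenumbers=k, absorbance=a)


def write_spectrum(s: Spectrum, path: str | Path) -> Path:
    """Write as two-column CSV with header, full double precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("wavenumber_cm-1,absorbance\n")
        for k, a in zip(s.wavenumbers, s.absorbance):
            fh.write(f"{float(k):.17g},{float(a):.17g}\n")
    return path


# ---------------------------------------------------------------------------
# cohorts

MANIFEST_COLUMNS = ["sample_id", "group", "file_path", "replicate", "wbc", "blasts"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "file_path": str})
    missing = {"sample_id", "group", "file_path"} - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    for col in ("wbc", "blasts"):
        if col not in df.columns:
            df[col] = np.nan
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValidationError(f"unrecognized group labels {sorted(bad)}; expected {GROUPS}")
    return df[MANIFEST_COLUMNS]


def load_cohort(manifest: str | Path | pd.DataFrame, base_dir: str | Path | None = None) -> CohortSet:
    """Load every spectrum a manifest references, attaching labels and counts."""
    if isinstance(manifest, (str, Path)):
        base_dir = base_dir or Path(manifest).parent
        manifest = read_manifest(manifest)
    base = Path(base_dir) if base_dir is not None else Path(".")
    spectra = []
    for row in manifest.itertuples(index=False):
        p = Path(row.file_path)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"sample {row.sample_id!r}: missing file {p}")
        s = read_spectrum(p, sample_id=str(row.sample_id))
        meta = {}
        if pd.notna(row.wbc):
            meta["wbc"] = float(row.wbc)
        if pd.notna(row.blasts):
            meta["blasts"] = float(row.blasts)
        spectra.append(
            replace(s, group=row.group, replicate=int(row.replicate), meta=meta)
        )
    return CohortSet(spectra)


def write_cohort(cohort: CohortSet, out_dir: str | Path) -> Path:
    """Write per-replicate CSV spectra plus a manifest CSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        fname = f"{s.sample_id}_r{s.replicate}.csv"
        write_spectrum(s, out / fname)
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "file_path": fname,
                "replicate": s.replicate,
                "wbc": s.meta.get("wbc", np.nan),
                "blasts": s.meta.get("blasts", np.nan),
            }
        )
    mpath = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(mpath, index=False)
    return mpath


def average_replicates(cohort: CohortSet) -> CohortSet:
    """Pointwise mean of each subject's replicates; one Spectrum per sample_id.

    All replicates of a subject must share a grid; resample first otherwise.
    """
    by_id: dict[str, list[Spectrum]] = {}
    for s in cohort:
        by_id.setdefault(s.sample_id, []).append(s)
    out = []
    for sid, reps in by_id.items():
        k0 = reps[0].wavenumbers
        for r in reps[1:]:
            if len(r) != len(reps[0]) or not np.array_equal(r.wavenumbers, k0):
                raise ValidationError(
                    f"sample {sid!r}: replicates on different grids; resample to a "
                    "common grid before averaging"
                )
        mean_a = np.mean([r.absorbance for r in reps], axis=0)
        out.append(replace(reps[0], replicate=1, absorbance=mean_a))
    return CohortSet(out, grid=cohort.grid)
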