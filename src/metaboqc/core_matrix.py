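"""Peak-matrix data model and I/O.

The central container is :class:`PeakMatrix`: an N samples x P features
table of chromatographic peak areas together with the sample metadata
(sample type, injection order, batch, dilution factor) and feature
metadata (m/z, retention time, QC flags) that every downstream quality
control stage needs.  Injection order is the time proxy throughout the
package: drift is modelled against it, and every operation preserves it.

Missing intensities are explicit (``NaN`` in memory, empty cell on disk)
and distinct from a measured zero.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleType",
    "SampleRecord",
    "FeatureRecord",
    "PeakMatrix",
    "PeakMatrixError",
    "read_peak_matrix",
    "write_peak_matrix",
    "drop_conditioning",
    "subset_by_type",
]


class PeakMatrixError(ValueError):
    """Raised when a peak matrix violates its structural invariants."""


class SampleType(str, enum.Enum):
    """Role of an injection in the analytical run."""

    BIOLOGICAL = "biological"
    POOLED_QC = "pooled_qc"
    CONDITIONING_QC = "conditioning_qc"
    PROCESS_BLANK = "process_blank"
    SYSTEM_BLANK = "system_blank"
    LTR = "ltr"
    SRM = "srm"
    DILUTION_QC = "dilution_qc"
    SUITABILITY = "suitability"


#: Sample types whose rows are "blank" injections.
BLANK_TYPES = frozenset({SampleType.PROCESS_BLANK, SampleType.SYSTEM_BLANK})

#: Reference samples corrected but never used to fit drift models.
REFERENCE_TYPES = frozenset({SampleType.LTR, SampleType.SRM})

# Required metadata columns, in on-disk order.
_META_COLUMNS = ("sample_id", "sample_type", "injection_order", "batch")
_OPTIONAL_META = ("dilution_factor", "vial_id")


@dataclasses.dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    sample_type: SampleType
    injection_order: int
    batch: int
    dilution_factor: float | None = None
    vial_id: str | None = None

    def __post_init__(self) -> None:
        if self.injection_order < 1:
            raise PeakMatrixError(
                f"injection_order must be a positive integer, got "
                f"{self.injection_order} for sample {self.sample_id!r}"
            )
        if self.batch < 1:
            raise PeakMatrixError(
                f"batch must be a positive integer, got {self.batch} "
                f"for sample {self.sample_id!r}"
            )
        if self.sample_type is SampleType.DILUTION_QC:
            if self.dilution_factor is None or not (0 < self.dilution_factor <= 1):
                raise PeakMatrixError(
                    f"dilution_qc sample {self.sample_id!r} needs a "
                    f"dilution_factor in (0, 1]"
                )
        elif self.dilution_factor is not None:
            raise PeakMatrixError(
                f"dilution_factor is only valid for dilution_qc samples "
                f"(sample {self.sample_id!r} is {self.sample_type.value})"
            )


@dataclasses.dataclass
class FeatureRecord:
    feature_id: str
    mz: float = np.nan
    rt: float = np.nan
    flags: set[str] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        if np.isfinite(self.mz) and self.mz <= 0:
            raise PeakMatrixError(f"feature {self.feature_id!r}: mz must be > 0")
        if np.isfinite(self.rt) and self.rt < 0:
            raise PeakMatrixError(f"feature {self.feature_id!r}: rt must be >= 0")


class PeakMatrix:
    """Samples x features intensity matrix with typed metadata.

    Parameters
    ----------
    samples
        Sequence of :class:`SampleRecord`.
    features
        Sequence of :class:`FeatureRecord`.
    intensities
        Array-like of shape ``(len(samples), len(features))``; ``NaN``
        marks a missing value.  All present values must be non-negative
        unless ``corrected=True`` (drift correction may legitimately
        produce small negative intensities, which are kept and counted).
    """

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        features: Sequence[FeatureRecord],
        intensities,
        *,
        corrected: bool = False,
    ) -> None:
        self.samples = list(samples)
        self.features = list(features)
        values = np.asarray(intensities, dtype=float)
        if values.shape != (len(self.samples), len(self.features)):
            raise PeakMatrixError(
                f"intensity shape {values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.features)} features"
            )
        self.intensities = values
        self.corrected = corrected
        self._validate()
        self._sort_by_injection_order()

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        dup = _duplicates(ids)
        if dup:
            raise PeakMatrixError(f"duplicate sample_id values: {sorted(dup)}")
        orders = [s.injection_order for s in self.samples]
        dup_t = _duplicates(orders)
        if dup_t:
            offenders = sorted(
                s.sample_id for s in self.samples if s.injection_order in dup_t
            )
            raise PeakMatrixError(
                f"duplicate injection_order values {sorted(dup_t)} shared by "
                f"samples {offenders}"
            )
        fids = [f.feature_id for f in self.features]
        dup_f = _duplicates(fids)
        if dup_f:
            raise PeakMatrixError(f"duplicate feature_id values: {sorted(dup_f)}")
        self._check_contiguous_batches()
        if not self.corrected:
            with np.errstate(invalid="ignore"):
                neg = np.nan_to_num(self.intensities, nan=0.0) < 0
            if neg.any():
                i, j = np.argwhere(neg)[0]
                raise PeakMatrixError(
                    f"negative intensity at sample "
                    f"{self.samples[int(i)].sample_id!r}, feature "
                    f"{self.features[int(j)].feature_id!r} in an uncorrected "
                    f"matrix"
                )

    def _check_contiguous_batches(self) -> None:
        # drift correction is per batch, so batches must partition the
        # injection order into contiguous runs
        ordered = sorted(self.samples, key=lambda s: s.injection_order)
        seen: set[int] = set()
        prev: int | None = None
        for s in ordered:
            if s.batch != prev:
                if s.batch in seen:
                    raise PeakMatrixError(
                        f"batch {s.batch} is not contiguous in injection order "
                        f"(re-entered at injection {s.injection_order})"
                    )
                seen.add(s.batch)
                prev = s.batch

    def _sort_by_injection_order(self) -> None:
        order = np.argsort([s.injection_order for s in self.samples], kind="stable")
        self.samples = [self.samples[i] for i in order]
        self.intensities = self.intensities[order, :]

    # -- accessors ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def injection_order(self) -> np.ndarray:
        return np.array([s.injection_order for s in self.samples], dtype=int)

    @property
    def batches(self) -> np.ndarray:
        return np.array([s.batch for s in self.samples], dtype=int)

    @property
    def sample_types(self) -> np.ndarray:
        return np.array([s.sample_type.value for s in self.samples], dtype=object)

    def type_mask(self, types: Iterable[SampleType | str]) -> np.ndarray:
        wanted = {SampleType(t) for t in types}
        return np.array([s.sample_type in wanted for s in self.samples], dtype=bool)

    def feature_index(self, feature_id: str) -> int:
        for j, f in enumerate(self.features):
            if f.feature_id == feature_id:
                return j
        raise KeyError(f"unknown feature_id {feature_id!r}")

    def feature_values(self, feature_id: str) -> np.ndarray:
        return self.intensities[:, self.feature_index(feature_id)]

    def copy(self) -> "PeakMatrix":
        return PeakMatrix(
            list(self.samples),
            [dataclasses.replace(f, flags=set(f.flags)) for f in self.features],
            self.intensities.copy(),
            corrected=self.corrected,
        )

    def select_samples(self, mask: np.ndarray) -> "PeakMatrix":
        """Row subset; intensity values are untouched."""
        mask = np.asarray(mask, dtype=bool)
        return PeakMatrix(
            [s for s, keep in zip(self.samples, mask) if keep],
            [dataclasses.replace(f, flags=set(f.flags)) for f in self.features],
            self.intensities[mask, :],
            corrected=self.corrected,
        )

    def select_features(self, keep_ids: Iterable[str]) -> "PeakMatrix":
        keep = set(keep_ids)
        idx = [j for j, f in enumerate(self.features) if f.feature_id in keep]
        return PeakMatrix(
            list(self.samples),
            [dataclasses.replace(self.features[j], flags=set(self.features[j].flags))
             for j in idx],
            self.intensities[:, idx],
            corrected=self.corrected,
        )

    def to_frame(self) -> pd.DataFrame:
        """Metadata + intensity columns as a single DataFrame (samples as rows)."""
        meta = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "sample_type": [s.sample_type.value for s in self.samples],
                "injection_order": self.injection_order,
                "batch": self.batches,
                "dilution_factor": [s.dilution_factor for s in self.samples],
                "vial_id": [s.vial_id for s in self.samples],
            }
        )
        data = pd.DataFrame(self.intensities, columns=self.feature_ids)
        return pd.concat([meta, data], axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakMatrix):
            return NotImplemented
        if self.samples != other.samples:
            return False
        if [dataclasses.astuple(f)[:3] for f in self.features] != [
            dataclasses.astuple(f)[:3] for f in other.features
        ]:
            return False
        if [f.flags for f in self.features] != [f.flags for f in other.features]:
            return False
        a, b = self.intensities, other.intensities
        return bool(np.array_equal(a, b, equal_nan=True))

    def __repr__(self) -> str:
        return (
            f"PeakMatrix({self.n_samples} samples x {self.n_features} features, "
            f"{int(np.isnan(self.intensities).sum())} missing)"
        )


def _duplicates(items: Sequence) -> set:
    seen: set = set()
    dup: set = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------
# I/O


def read_peak_matrix(
    path: str | Path,
    metadata_spec: Mapping[str, str] | None = None,
    *,
    feature_metadata: str | Path | None = None,
    sep: str | None = None,
    transpose: bool = False,
    corrected: bool = False,
) -> PeakMatrix:
    """Read a peak matrix from CSV/TSV.

    ``metadata_spec`` maps the canonical metadata names (``sample_id``,
    ``sample_type``, ``injection_order``, ``batch``, optionally
    ``dilution_factor`` and ``vial_id``) to the column names used in the
    file; canonical names are assumed where the mapping is absent.  All
    remaining columns are feature intensities.  Empty cells denote
    missing values.  Set ``transpose=True`` for the features-as-rows
    dialect common in vendor exports (samples as columns, metadata in
    the leading rows).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if transpose:
        raw = raw.set_index(raw.columns[0]).T.reset_index(names="sample_id")
    spec = dict(metadata_spec or {})
    colmap = {spec.get(name, name): name for name in _META_COLUMNS + _OPTIONAL_META}
    present = {c: colmap[c] for c in raw.columns if c in colmap}
    raw = raw.rename(columns=present)
    missing_meta = [c for c in _META_COLUMNS if c not in raw.columns]
    if missing_meta:
        raise PeakMatrixError(f"missing required metadata columns: {missing_meta}")

    samples: list[SampleRecord] = []
    for i, row in raw.iterrows():
        stype = row["sample_type"].strip()
        try:
            sample_type = SampleType(stype)
        except ValueError:
            raise PeakMatrixError(
                f"unknown sample_type {stype!r} at row {i + 2} "
                f"(sample {row['sample_id']!r})"
            ) from None
        dil = row.get("dilution_factor", "")
        vial = row.get("vial_id", "")
        samples.append(
            SampleRecord(
                sample_id=row["sample_id"],
                sample_type=sample_type,
                injection_order=_parse_int(row["injection_order"], i, "injection_order"),
                batch=_parse_int(row["batch"], i, "batch"),
                dilution_factor=float(dil) if dil not in ("", "NA") else None,
                vial_id=vial or None,
            )
        )

    feature_cols = [c for c in raw.columns if c not in _META_COLUMNS + _OPTIONAL_META]
    values = np.full((len(samples), len(feature_cols)), np.nan)
    for j, col in enumerate(feature_cols):
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell in ("", "NA", "NaN", "nan"):
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise PeakMatrixError(
                    f"non-numeric intensity {cell!r} at row {i + 2}, "
                    f"column {col!r}"
                ) from None

    features = [FeatureRecord(feature_id=c) for c in feature_cols]
    if feature_metadata is not None:
        features = _read_feature_sidecar(feature_metadata, feature_cols)
    return PeakMatrix(samples, features, values, corrected=corrected)


def _parse_int(cell: str, row: int, name: str) -> int:
    try:
        return int(float(cell))
    except ValueError:
        raise PeakMatrixError(f"non-integer {name} {cell!r} at row {row + 2}") from None


def _read_feature_sidecar(path: str | Path, feature_ids: Sequence[str]) -> list[FeatureRecord]:
    tab = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).set_index(
        "feature_id"
    )
    records = []
    for fid in feature_ids:
        if fid in tab.index:
            row = tab.loc[fid]
            flags = set(filter(None, row.get("flags", "").split(";")))
            records.append(
                FeatureRecord(
                    feature_id=fid,
                    mz=float(row["mz"]) if row.get("mz", "") else np.nan,
                    rt=float(row["rt"]) if row.get("rt", "") else np.nan,
                    flags=flags,
                )
            )
        else:
            records.append(FeatureRecord(feature_id=fid))
    return records


def write_peak_matrix(
    matrix: PeakMatrix,
    path: str | Path,
    *,
    feature_metadata: str | Path | None = None,
) -> None:
    """Write a TSV peak matrix (metadata columns first, then features).

    Missing intensities become empty cells.  If ``feature_metadata`` is
    given, a sidecar TSV with feature_id, mz, rt and semicolon-joined
    flags is written as well.  Output is bit-stable for identical input.
    """
    path = Path(path)
    frame = matrix.to_frame()
    frame["dilution_factor"] = [
        "" if v is None else repr(float(v)) for v in frame["dilution_factor"]
    ]
    frame["vial_id"] = ["" if v is None else v for v in frame["vial_id"]]
    for fid in matrix.feature_ids:
        frame[fid] = [_format_value(v) for v in frame[fid]]
    frame.to_csv(path, sep="\t", index=False)
    if feature_metadata is not None:
        rows = []
        for f in matrix.features:
            rows.append(
                {
                    "feature_id": f.feature_id,
                    "mz": "" if not np.isfinite(f.mz) else repr(float(f.mz)),
                    "rt": "" if not np.isfinite(f.rt) else repr(float(f.rt)),
                    "flags": ";".join(sorted(f.flags)),
                }
            )
        pd.DataFrame(rows, columns=["feature_id", "mz", "rt", "flags"]).to_csv(
            feature_metadata, sep="\t", index=False
        )


def _format_value(v: float) -> str:
    if np.isnan(v):
        return ""
    return repr(float(v))


# ---------------------------------------------------------------------
# Row-subset operations


def drop_conditioning(matrix: PeakMatrix) -> PeakMatrix:
    """Remove conditioning-QC injections.

    Conditioning injections equilibrate the platform and their data are
    discarded before any QC statistic is computed; this must run before
    metrics or drift correction.
    """
    mask = ~matrix.type_mask({SampleType.CONDITIONING_QC})
    n_removed = int((~mask).sum())
    out = matrix.select_samples(mask)
    if out.n_samples == 0:
        warnings.warn("all samples were conditioning injections; matrix is empty")
    if n_removed:
        out.n_conditioning_removed = n_removed  # type: ignore[attr-defined]
    return out


def subset_by_type(
    matrix: PeakMatrix, types: Iterable[SampleType | str]
) -> PeakMatrix:
    """Rows whose sample_type is in ``types``, injection order preserved."""
    types = set(types)
    if not types:
        raise PeakMatrixError("types must be non-empty")
    out = matrix.select_samples(matrix.type_mask(types))
    if out.n_samples == 0:
        warnings.warn(
            f"no samples of type {sorted(SampleType(t).value for t in types)} present"
        )
    return out
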