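"""Reading, writing and aligning multi-omics feature matrices.

Feature matrices arrive as delimited text (TSV/CSV, optionally in the GCT 1.2
dialect) with one axis of sample identifiers and one axis of feature
identifiers.  Sample identifiers may be TCGA-style barcodes, in which case the
two-digit sample-type code (field 4) distinguishes tumor samples (codes 01-09)
from normals and controls.

All downstream stages operate on :class:`AlignedDataset`: a list of
:class:`FeatureView` objects sharing one sample ordering plus a
:class:`LabelSet` on that same ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureView",
    "LabelSet",
    "AlignedDataset",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_label_file",
    "write_label_file",
    "parse_tcga_sample_type",
    "filter_tumor_samples",
    "align_views",
    "dataset_manifest",
]

TUMOR_CODE_RANGE = (1, 9)


@dataclass
class FeatureView:
    """One omics view: an n_samples x p real matrix with sample identifiers."""

    name: str
    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError(f"view {self.name!r}: matrix must be 2-D")
        n, p = self.matrix.shape
        if n < 2:
            raise ValueError(f"view {self.name!r}: need at least 2 samples, got {n}")
        if p < 1:
            raise ValueError(f"view {self.name!r}: need at least 1 feature")
        if len(self.sample_ids) != n:
            raise ValueError(
                f"view {self.name!r}: {len(self.sample_ids)} ids for {n} rows"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"view {self.name!r}: duplicate sample ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"view {self.name!r}: non-finite values in matrix")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset(self, ids: Sequence[str]) -> "FeatureView":
        """Restrict/reorder to ``ids`` (all of which must be present)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as exc:
            raise KeyError(f"view {self.name!r}: unknown sample id {exc}") from None
        return FeatureView(self.name, list(ids), self.matrix[rows])


@dataclass
class LabelSet:
    """Subtype label per sample; ``classes`` is the sorted distinct label list."""

    sample_ids: list[str]
    labels: list[str]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels must have equal length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in label set")
        if not self.classes:
            self.classes = sorted(set(self.labels))
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside declared classes: {sorted(unknown)}")

    def subset(self, ids: Sequence[str]) -> "LabelSet":
        lookup = dict(zip(self.sample_ids, self.labels))
        try:
            labels = [lookup[s] for s in ids]
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc} in label set") from None
        return LabelSet(list(ids), labels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)


@dataclass
class AlignedDataset:
    """Views and labels sharing one sample ordering."""

    views: list[FeatureView]
    labels: LabelSet

    def __post_init__(self) -> None:
        ref = self.labels.sample_ids
        for v in self.views:
            if v.sample_ids != ref:
                raise ValueError(
                    f"view {v.name!r} sample ordering differs from label ordering"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.labels.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.labels.sample_ids)


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited matrix, skipping a GCT 1.2 preamble when present."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"{path}: empty file")
        skiprows = 0
        if first.startswith("#1.2"):
            fh.readline()  # dimensions line
            skiprows = 2
            first = fh.readline()
    sep = _sniff_delimiter(first)
    df = pd.read_csv(path, sep=sep, skiprows=skiprows, index_col=0, header=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty matrix")
    # GCT files carry a Description column after the id column; drop it.
    if skiprows == 2 and df.columns[0].lower() in {"description", "desc"}:
        df = df.drop(columns=df.columns[0])
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate row ids")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate column ids")
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        bad = body.isna().to_numpy().nonzero()
        r, c = bad[0][0], bad[1][0]
        raise ValueError(
            f"{path}: non-numeric or missing cell at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return body


def read_feature_matrix(
    path: str | Path,
    name: str | None = None,
    orientation: str = "auto",
    known_sample_ids: Sequence[str] | None = None,
    impute_missing: bool = False,
) -> FeatureView:
    """Read a delimited feature matrix into a samples-in-rows ``FeatureView``.

    Parameters
    ----------
    orientation:
        ``samples_in_rows``, ``samples_in_columns`` or ``auto``.  With
        ``auto``, if ``known_sample_ids`` is given the axis with the larger
        id overlap is taken as the sample axis; otherwise samples are assumed
        to be in columns (the features-in-rows convention of GDAC/GCT
        expression matrices).
    impute_missing:
        when True, NA cells are replaced by the feature-wise mean instead of
        raising.
    """
    if orientation not in {"samples_in_rows", "samples_in_columns", "auto"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if impute_missing:
        df = _read_table_imputed(path)
    else:
        df = _read_table(path)
    if orientation == "auto":
        if known_sample_ids is not None:
            known = set(map(str, known_sample_ids))
            rows = len(known.intersection(map(str, df.index)))
            cols = len(known.intersection(map(str, df.columns)))
            orientation = "samples_in_rows" if rows > cols else "samples_in_columns"
        else:
            orientation = "samples_in_columns"
    if orientation == "samples_in_columns":
        df = df.T
    return FeatureView(
        name=name or path.stem,
        sample_ids=[str(s) for s in df.index],
        matrix=df.to_numpy(dtype=float),
    )


def _read_table_imputed(path: Path) -> pd.DataFrame:
    """Like ``_read_table`` but NA cells become the column (feature) mean."""
    try:
        return _read_table(path)
    except ValueError as exc:
        if "non-numeric" not in str(exc):
            raise
    with open(path) as fh:
        first = fh.readline()
    skiprows = 2 if first.startswith("#1.2") else 0
    sep = _sniff_delimiter(first if skiprows == 0 else open(path).readlines()[2])
    df = pd.read_csv(path, sep=sep, skiprows=skiprows, index_col=0, header=0)
    body = df.apply(pd.to_numeric, errors="coerce")
    return body.fillna(body.mean())


def write_feature_matrix(
    view: FeatureView, path: str | Path, orientation: str = "samples_in_columns"
) -> None:
    """Write a view as TSV; default orientation is features-in-rows."""
    df = pd.DataFrame(view.matrix, index=view.sample_ids)
    df.columns = [f"f{j}" for j in range(view.n_features)]
    if orientation == "samples_in_columns":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t", index_label="id")


def read_label_file(path: str | Path) -> LabelSet:
    """Read a two-column (sample_id, subtype) delimited file."""
    with open(path) as fh:
        first = fh.readline()
    sep = _sniff_delimiter(first)
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: label file needs two columns (id, subtype)")
    return LabelSet(list(df.iloc[:, 0]), list(df.iloc[:, 1]))


def write_label_file(labels: LabelSet, path: str | Path) -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "subtype": labels.labels}).to_csv(
        path, sep="\t", index=False
    )


def parse_tcga_sample_type(barcode: str) -> int:
    """Return the two-digit sample-type code from a TCGA-style barcode.

    The code is the leading two digits of the fourth dash-separated field,
    e.g. ``TCGA-AB-1234-01A`` -> 1 (primary tumor), ``...-11B`` -> 11
    (solid tissue normal).
    """
    fields = str(barcode).split("-")
    if len(fields) < 4:
        raise ValueError(f"malformed barcode {barcode!r}: fewer than 4 fields")
    code = fields[3][:2]
    if len(code) < 2 or not code.isdigit():
        raise ValueError(f"malformed barcode {barcode!r}: sample-type field {code!r}")
    return int(code)


def filter_tumor_samples(view: FeatureView) -> FeatureView:
    """Keep samples whose barcode type code is in 01-09 (tumor), order kept."""
    lo, hi = TUMOR_CODE_RANGE
    keep = [s for s in view.sample_ids if lo <= parse_tcga_sample_type(s) <= hi]
    if not keep:
        raise ValueError(f"view {view.name!r}: no tumor samples (codes 01-09) remain")
    if keep == view.sample_ids:
        return view
    return view.subset(keep)


def _patient_key(barcode: str) -> str:
    """First three barcode fields (project-site-patient)."""
    return "-".join(str(barcode).split("-")[:3])


def align_views(
    views: Sequence[FeatureView],
    labels: LabelSet,
    match_on_patient: bool = True,
) -> AlignedDataset:
    """Intersect sample ids across views and labels; sort lexicographically.

    Exact-id intersection is attempted first.  If it is empty,
    ``match_on_patient`` falls back to matching on the first three barcode
    fields (the patient id), which tolerates vial/analyte suffixes differing
    between views; the patient key then becomes the canonical sample id.
    """
    if not views:
        raise ValueError("need at least one view")
    common = set(labels.sample_ids)
    for v in views:
        common &= set(v.sample_ids)
    if common:
        order = sorted(common)
        return AlignedDataset(
            views=[v.subset(order) for v in views], labels=labels.subset(order)
        )
    if not match_on_patient:
        raise ValueError("no common sample ids across views and labels")

    def keyed(ids: Sequence[str], what: str) -> dict[str, str]:
        out: dict[str, str] = {}
        for s in ids:
            k = _patient_key(s)
            if k in out:
                raise ValueError(f"{what}: duplicate patient key {k!r}")
            out[k] = s
        return out

    maps = [keyed(v.sample_ids, f"view {v.name!r}") for v in views]
    lmap = keyed(labels.sample_ids, "labels")
    ckeys = set(lmap)
    for m in maps:
        ckeys &= set(m)
    if not ckeys:
        raise ValueError("no common samples across views and labels (patient match)")
    order = sorted(ckeys)
    new_views = []
    for v, m in zip(views, maps):
        sub = v.subset([m[k] for k in order])
        new_views.append(FeatureView(v.name, order, sub.matrix))
    lsub = labels.subset([lmap[k] for k in order])
    return AlignedDataset(
        views=new_views, labels=LabelSet(order, lsub.labels, lsub.classes)
    )


def dataset_manifest(dataset: AlignedDataset) -> dict:
    """JSON-ready summary: per-class sample counts and per-view dimensions."""
    counts: dict[str, int] = {c: 0 for c in dataset.labels.classes}
    for l in dataset.labels.labels:
        counts[l] += 1
    return {
        "n_samples": dataset.n_samples,
        "classes": dataset.labels.classes,
        "class_counts": counts,
        "views": {v.name: {"n_features": v.n_features} for v in dataset.views},
    }


def write_manifest(dataset: AlignedDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataset_manifest(dataset), fh, indent=2, sort_keys=True)
        fh.write("\n")
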