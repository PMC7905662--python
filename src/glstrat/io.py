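"""Readers and writers for the plain-text formats used throughout the pipeline.

All tabular inputs are TSV with a header row; gene sets use the Broad GMT
dialect.  Readers are strict: malformed input raises :class:`FormatError`
naming the offending row/column instead of silently truncating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CODING = "coding"
LNCRNA = "lncRNA"
FEATURE_CLASSES = (CODING, LNCRNA)


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with an optional feature-class label.

    ``values`` is a features-by-samples DataFrame of non-negative integers;
    ``feature_class`` (if present) maps each feature to ``coding``/``lncRNA``.
    """

    values: pd.DataFrame
    feature_class: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0):
                i, j = np.argwhere(arr != np.round(arr))[0]
                raise FormatError(
                    f"non-integer count at ({v.index[i]}, {v.columns[j]})"
                )
            self.values = v.astype(np.int64)
            arr = self.values.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(f"negative count at ({v.index[i]}, {v.columns[j]})")
        if self.feature_class is not None:
            fc = self.feature_class.reindex(v.index)
            if fc.isna().any():
                raise FormatError("feature_class missing for some features")
            bad = set(fc.unique()) - set(FEATURE_CLASSES)
            if bad:
                raise FormatError(f"unknown feature class {sorted(bad)}")
            self.feature_class = fc

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def features_of_class(self, cls: str) -> list[str]:
        if self.feature_class is None:
            raise ValueError("matrix carries no feature_class annotation")
        return list(self.feature_class.index[self.feature_class == cls])

    def subset_features(self, features) -> "CountMatrix":
        fc = None if self.feature_class is None else self.feature_class.loc[list(features)]
        return CountMatrix(self.values.loc[list(features)], fc)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> set of feature ids."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample survival data: follow-up time in days and event indicator."""

    table: pd.DataFrame  # index sample_id; columns time, event, extras

    def __post_init__(self) -> None:
        t = self.table
        for col in ("time", "event"):
            if col not in t.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        if t.index.duplicated().any():
            raise FormatError("duplicate sample id in clinical table")
        if (t["time"].to_numpy() < 0).any():
            bad = t.index[t["time"] < 0][0]
            raise FormatError(f"negative time for sample {bad!r}")
        ev = t["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            bad = t.index[~t["event"].isin((0, 1))][0]
            raise FormatError(f"event not in {{0,1}} for sample {bad!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def time(self) -> pd.Series:
        return self.table["time"]

    @property
    def event(self) -> pd.Series:
        return self.table["event"]


@dataclass
class RegulonCollection:
    """TF regulons: tf id -> list of (target id, mode) with mode in {+1, -1}."""

    regulons: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tf, targets in self.regulons.items():
            ids = [t for t, _ in targets]
            if len(ids) != len(set(ids)):
                raise FormatError(f"duplicate target within regulon {tf!r}")
            for t, mode in targets:
                if mode not in (1, -1):
                    raise FormatError(f"mode {mode!r} for ({tf}, {t}) not in {{+1,-1}}")

    def __len__(self) -> int:
        return len(self.regulons)

    def __getitem__(self, tf: str) -> list[tuple[str, int]]:
        return self.regulons[tf]

    def names(self) -> list[str]:
        return list(self.regulons)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _check_duplicate_header(path) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen: set[str] = set()
    for col in header[1:]:
        if col in seen:
            raise FormatError(f"duplicate column {col!r} in {path}")
        seen.add(col)


def read_counts(path) -> CountMatrix:
    """Read a gene x sample TSV of integer counts.

    First column holds the feature id; an optional ``feature_class`` column
    labels features coding/lncRNA; remaining columns are samples.
    """
    _check_duplicate_header(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    fc = None
    if "feature_class" in df.columns:
        fc = df.pop("feature_class")
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"non-numeric count value in {path}")
    return CountMatrix(df, fc)


def write_counts(matrix: CountMatrix, path) -> None:
    df = matrix.values.copy()
    if matrix.feature_class is not None:
        df.insert(0, "feature_class", matrix.feature_class)
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_matrix(path, allow_na: bool = True) -> pd.DataFrame:
    """Read a real-valued feature x sample TSV (CNV scores, methylation betas)."""
    _check_duplicate_header(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.duplicated().any():
        raise FormatError(f"duplicate feature id in {path}")
    if not allow_na and df.isna().any().any():
        raise FormatError(f"missing values not permitted in {path}")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id", na_rep="NA")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: gene set with zero members")
            name, desc, members = parts[0], parts[1], parts[2:]
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set with zero members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            if len(members) != len(set(members)):
                logger.warning("duplicate members within set %r deduplicated", name)
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# clinical / mutations / regulons
# ---------------------------------------------------------------------------


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise FormatError(f"clinical table {path} missing 'sample' column")
    df = df.set_index("sample")
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", index_label="sample")


def read_binary_matrix(path) -> pd.DataFrame:
    """Read a binary feature x sample matrix (e.g. nonsilent-mutation calls)."""
    _check_duplicate_header(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        i, j = np.argwhere(~np.isin(arr, (0, 1)))[0]
        raise FormatError(
            f"non-binary value {arr[i, j]!r} at ({df.index[i]}, {df.columns[j]})"
        )
    return df.astype(np.int8)


def write_binary_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_regulons(path) -> RegulonCollection:
    df = pd.read_csv(path, sep="\t")
    for col in ("tf", "target", "mode"):
        if col not in df.columns:
            raise FormatError(f"regulon table {path} missing column {col!r}")
    regs: dict[str, list[tuple[str, int]]] = {}
    for tf, target, mode in df[["tf", "target", "mode"]].itertuples(index=False):
        try:
            mode = int(mode)
        except (TypeError, ValueError):
            raise FormatError(f"mode {mode!r} for ({tf}, {target}) not integer")
        regs.setdefault(str(tf), []).append((str(target), mode))
    return RegulonCollection(regs)


def write_regulons(collection: RegulonCollection, path) -> None:
    rows = [
        (tf, target, f"{mode:+d}")
        for tf in collection.names()
        for target, mode in collection[tf]
    ]
    pd.DataFrame(rows, columns=["tf", "target", "mode"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# alignment helper
# ---------------------------------------------------------------------------


def align_samples(first: list[str], *others: list[str]) -> list[str]:
    """Intersect sample-id lists, preserving the order of the first."""
    keep = set(first)
    for ids in others:
        keep &= set(ids)
    return [s for s in first if s in keep]
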