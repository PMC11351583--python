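"""Readers, writers and bundled fixtures for the tabular formats of the pipeline.

Canonical dialect for every table: UTF-8 TSV, ``.`` decimal point, no thousands
separators, one header row, ``\\n`` line endings.  Identifier namespaces are gene
symbols for mRNA and miRBase mature names (``hsa-...-5p/3p``) for miRNA; matching
everywhere is exact string match after whitespace trimming, with no alias
resolution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("mirlink")

__all__ = [
    "FormatError",
    "CountMatrix",
    "SampleTable",
    "GeneSetCollection",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_gmt",
    "write_gmt",
    "read_pair_table",
    "write_pair_table",
    "load_fixture",
    "FIXTURE_NAMES",
]


class FormatError(ValueError):
    """A file does not conform to its documented format."""


# conditions accepted in sample tables; ACM is the study's case label
_CASE_ALIASES = {"case", "acm"}
_CONTROL_ALIASES = {"control", "ctrl", "healthy"}


class CountMatrix:
    """Non-negative integer feature-by-sample count matrix.

    Thin wrapper around a pandas DataFrame (features as index, samples as
    columns) that enforces the container invariants: unique feature and sample
    identifiers and non-negative integral counts.
    """

    def __init__(self, frame: pd.DataFrame, meta: dict | None = None):
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if frame.columns.has_duplicates:
            dup = frame.columns[frame.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        values = frame.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere(values != np.floor(values))
                f, s = (frame.index[bad[0][0]], frame.columns[bad[0][1]]) if len(bad) else ("?", "?")
                raise FormatError(f"non-integer count at feature {f!r}, sample {s!r}")
            values = values.astype(np.int64)
        if values.size and values.min() < 0:
            f, s = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at feature {frame.index[f]!r}, sample {frame.columns[s]!r}"
            )
        self.frame = pd.DataFrame(
            values.astype(np.int64), index=frame.index.astype(str), columns=frame.columns.astype(str)
        )
        self.meta = dict(meta or {})

    @property
    def feature_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.frame.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return CountMatrix(self.frame[list(sample_ids)], meta=self.meta)

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self.frame.equals(other.frame)

    def __repr__(self) -> str:
        return f"CountMatrix({self.shape[0]} features x {self.shape[1]} samples)"


class SampleTable:
    """Sample-to-condition assignment for a two-group (case vs control) design."""

    def __init__(self, frame: pd.DataFrame):
        if not {"sample_id", "condition"}.issubset(frame.columns):
            raise FormatError("sample table requires columns (sample_id, condition)")
        frame = frame[["sample_id", "condition"]].copy()
        frame["sample_id"] = frame["sample_id"].astype(str).str.strip()
        cond = frame["condition"].astype(str).str.strip().str.lower()
        norm = []
        for sid, c in zip(frame["sample_id"], cond):
            if c in _CASE_ALIASES:
                norm.append("case")
            elif c in _CONTROL_ALIASES:
                norm.append("control")
            else:
                raise FormatError(f"unknown condition {c!r} for sample {sid!r}")
        frame["condition"] = norm
        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r} in sample table")
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def case_ids(self) -> list[str]:
        return list(self.frame.loc[self.frame["condition"] == "case", "sample_id"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.frame.loc[self.frame["condition"] == "control", "sample_id"])

    def indicator(self, sample_ids: list[str]) -> np.ndarray:
        """0/1 case indicator aligned to `sample_ids` (1 = case)."""
        cond = dict(zip(self.frame["sample_id"], self.frame["condition"]))
        missing = [s for s in sample_ids if s not in cond]
        if missing:
            raise KeyError(f"samples missing from sample table: {missing}")
        return np.array([1 if cond[s] == "case" else 0 for s in sample_ids], dtype=float)

    def check_paired(self, counts: CountMatrix, min_per_group: int = 2) -> None:
        if set(self.sample_ids) != set(counts.sample_ids):
            raise FormatError("sample table and count matrix carry different sample sets")
        if len(self.case_ids) < min_per_group or len(self.control_ids) < min_per_group:
            raise FormatError(f"need at least {min_per_group} samples per condition")

    def __repr__(self) -> str:
        return f"SampleTable({len(self.case_ids)} case vs {len(self.control_ids)} control)"


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, plus the background universe."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
        if self.universe is None:
            self.universe = set().union(*self.sets.values()) if self.sets else set()

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# count matrices


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a canonical-dialect count TSV (first column feature ids, header = sample ids)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as TSV: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    frame.index = frame.index.astype(str).str.strip()
    parsed = pd.DataFrame(index=frame.index)
    for col in frame.columns:
        cell = pd.to_numeric(frame[col].str.strip(), errors="coerce")
        bad = cell.isna() | (cell != np.floor(cell.fillna(0)))
        if bad.any():
            feat = frame.index[bad.to_numpy()][0]
            raise FormatError(f"{path}: non-integer count for feature {feat!r}, sample {col!r}")
        if (cell < 0).any():
            feat = frame.index[(cell < 0).to_numpy()][0]
            raise FormatError(f"{path}: negative count for feature {feat!r}, sample {col!r}")
        parsed[col] = cell.astype(np.int64)
    parsed.index.name = frame.index.name or "feature_id"
    return CountMatrix(parsed)


def write_count_matrix(counts: CountMatrix, path: str | Path) -> None:
    frame = counts.frame.copy()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", lineterminator="\n")


def read_sample_table(path: str | Path) -> SampleTable:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return SampleTable(frame)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read standard GMT (name TAB description TAB member...), one set per line."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, desc, *members = fields
            name = name.strip()
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = {m.strip() for m in members if m.strip()}
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name in collection.set_names:
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            handle.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# miRNA-gene pair tables

_PAIR_COLUMNS = {"prediction": ("mirna", "gene", "tool"), "validation": ("mirna", "gene", "source")}


def read_pair_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a prediction (mirna, gene, tool) or validation (mirna, gene, source) TSV.

    Duplicate triples are collapsed with a logged warning count.
    """
    if kind not in _PAIR_COLUMNS:
        raise ValueError(f"kind must be one of {sorted(_PAIR_COLUMNS)}, got {kind!r}")
    cols = _PAIR_COLUMNS[kind]
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing} for kind={kind!r}")
    frame = frame[list(cols)].copy()
    for c in cols:
        frame[c] = frame[c].astype(str).str.strip()
    n_before = len(frame)
    frame = frame.drop_duplicates().reset_index(drop=True)
    n_dup = n_before - len(frame)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate %s triple(s)", path, n_dup, kind)
    return frame


def write_pair_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# bundled fixtures

FIXTURE_NAMES = ("table2_counts", "published_pairs", "dem_list")


def _fixture_path(filename: str) -> Path:
    return Path(resources.files("mirlink.fixtures") / filename)


def load_fixture(name: str):
    """Load a bundled in-study fixture.

    ``table2_counts``
        The 59 miRNA x 7 sample printed count matrix (4 case, 3 control), as a
        CountMatrix with transcription metadata attached.
    ``published_pairs``
        The 11 reported negatively correlated miRNA-target pairs, as a list of
        (mirna, gene) tuples.
    ``dem_list``
        The 8 reported differentially expressed miRNAs with printed direction,
        as a DataFrame with columns (mirna, direction).
    """
    if name == "table2_counts":
        counts = read_count_matrix(_fixture_path("table2_counts.tsv"))
        counts.meta.update(json.loads(_fixture_path("table2_counts.meta.json").read_text()))
        return counts
    if name == "published_pairs":
        frame = pd.read_csv(_fixture_path("published_pairs.tsv"), sep="\t", dtype=str)
        return list(frame.itertuples(index=False, name=None))
    if name == "dem_list":
        return pd.read_csv(_fixture_path("dem_list.tsv"), sep="\t", dtype=str)
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")


def table2_sample_table() -> SampleTable:
    """Condition assignment for the table2_counts fixture (4 case vs 3 control)."""
    meta = json.loads(_fixture_path("table2_counts.meta.json").read_text())
    rows = [(s, "case") for s in meta["case_samples"]] + [
        (s, "control") for s in meta["control_samples"]
    ]
    return SampleTable(pd.DataFrame(rows, columns=["sample_id", "condition"]))
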