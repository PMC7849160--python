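"""Validated containers and TSV/Newick readers for the analysis.

Canonical on-disk dialects: tab-separated UTF-8 tables with feature identifiers
in the first column and sample identifiers in the header row; rooted Newick
trees with branch lengths on every edge. Missing cells are errors, never
silently treated as zeros.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

DESIGN_DILUTION_EXPONENTS = (-1, -4, -7, -10)

__all__ = [
    "CountTable",
    "SampleMetadata",
    "AnalysisConfig",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "read_newick",
    "CoverageError",
    "IdentifierError",
    "TableFormatError",
]


class IdentifierError(ValueError):
    """Duplicate or unknown feature/sample/tip identifiers."""


class TableFormatError(ValueError):
    """Malformed table cell or structure."""


class CoverageError(ValueError):
    """A sample required by one artifact is missing from another."""


@dataclass
class CountTable:
    """Feature x sample abundance matrix.

    Values are non-negative; integer counts unless ``is_normalized`` is set,
    in which case every sample column sums to one (relative abundances).
    """

    data: pd.DataFrame  # rows = features, columns = samples
    is_normalized: bool = False

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise IdentifierError(f"duplicate feature id: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise IdentifierError(f"duplicate sample id: {dup!r}")
        if df.isna().any().any():
            r, c = next(zip(*np.where(df.isna().to_numpy())))
            raise TableFormatError(
                f"missing/non-numeric cell at feature {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise TableFormatError("non-numeric values in table")
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise TableFormatError(
                f"negative value at feature {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if self.is_normalized:
            sums = vals.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = df.columns[int(np.argmax(np.abs(sums - 1.0)))]
                raise TableFormatError(f"normalized table column {bad!r} does not sum to 1")

    @property
    def features(self) -> list:
        return list(self.data.index)

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids: Sequence) -> "CountTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise CoverageError(f"samples absent from table: {missing[:5]}")
        return CountTable(self.data.loc[:, list(sample_ids)].copy(), self.is_normalized)


@dataclass
class SampleMetadata:
    """Per-sample design variables for the dilution x pH microcosm layout."""

    table: pd.DataFrame  # index = sample id; columns dilution_exponent, pH, replicate
    grouping_key: str = "dilution"  # "dilution" or "dilution_pH"

    def __post_init__(self) -> None:
        t = self.table
        required = {"dilution_exponent", "pH", "replicate"}
        if not required <= set(t.columns):
            raise TableFormatError(f"metadata missing columns: {sorted(required - set(t.columns))}")
        if t.index.duplicated().any():
            raise IdentifierError("duplicate sample id in metadata")
        bad = set(t["dilution_exponent"]) - set(DESIGN_DILUTION_EXPONENTS)
        if bad:
            raise ValueError(
                f"dilution exponent(s) {sorted(bad)} outside the design levels "
                f"{DESIGN_DILUTION_EXPONENTS}"
            )
        if ((t["pH"] < 4.5) | (t["pH"] > 8.5)).any():
            raise ValueError("pH outside design range 4.5-8.5")
        if self.grouping_key not in ("dilution", "dilution_pH"):
            raise ValueError(f"unknown grouping key {self.grouping_key!r}")

    @property
    def samples(self) -> list:
        return list(self.table.index)

    def group_labels(self) -> pd.Series:
        """Group label per sample, a pure function of the grouping key."""
        exps = self.table["dilution_exponent"]
        dil = exps.map(lambda e: f"10^{e}")
        if self.grouping_key == "dilution":
            return dil.rename("group")
        ph = self.table["pH"].map(lambda v: f"pH{v:g}")
        return (dil + "_" + ph).rename("group")

    def groups(self) -> dict[str, list]:
        """Mapping group label -> ordered sample ids."""
        labels = self.group_labels()
        out: dict[str, list] = {}
        for sid, lab in labels.items():
            out.setdefault(lab, []).append(sid)
        return out

    def require_cover(self, table: CountTable) -> None:
        missing = [s for s in table.samples if s not in self.table.index]
        if missing:
            raise CoverageError(f"samples without metadata: {missing[:5]}")


@dataclass
class AnalysisConfig:
    """Printed constants of the analysis, collected in one place."""

    rarefaction_depth: int = 11020
    avd_grouping: str = "dilution"
    r_min: float = 0.75
    q_max: float = 0.01
    null_ensemble_size: int = 100
    bnti_null_draws: int = 999
    cv_folds: int = 10
    cv_repeats: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r_min < 1:
            raise ValueError("r_min must be in (0, 1)")
        if not 0 < self.q_max < 1:
            raise ValueError("q_max must be in (0, 1)")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction depth must be >= 1")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def read_count_table(path: str | Path) -> CountTable:
    """Read a feature x sample TSV (feature ids in column 1, samples in header)."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    # pandas mangles duplicate headers to s1.1 etc.; detect from the raw header
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise IdentifierError("duplicate sample id in header")
    df.columns = header
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise TableFormatError(
                f"non-numeric cell in sample {col!r}, feature {bad.index[0]!r}"
            )
    return CountTable(df)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(
    path: str | Path, grouping_key: str = "dilution", counts: CountTable | None = None
) -> SampleMetadata:
    """Read a sample metadata TSV (columns: sample, dilution_exponent, pH, replicate)."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise TableFormatError("metadata must have a 'sample' column")
    meta = SampleMetadata(df.set_index("sample"), grouping_key=grouping_key)
    if counts is not None:
        meta.require_cover(counts)
    return meta


def _check_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if any(n is None for n in tips):
        raise IdentifierError("unlabeled tip in tree")
    if len(set(tips)) != len(tips):
        dup = pd.Series(tips)
        raise IdentifierError(f"duplicate tip label: {dup[dup.duplicated()].iloc[0]!r}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise TableFormatError("branch without length (no silent default)")
        if node.length < 0:
            raise TableFormatError("negative branch length")
    return tree


def read_newick(source: str | Path | io.StringIO) -> TreeNode:
    """Read and validate a single rooted Newick tree with branch lengths.

    Accepts a path or an in-memory Newick string.
    """
    if isinstance(source, str) and source.lstrip().startswith("("):
        source = io.StringIO(source)
    tree = TreeNode.read(source, format="newick")
    if tree.length is None:
        tree.length = 0.0  # root edge carries no information
    return _check_tree(tree)
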