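"""Input/output: abundance tables, Newick trees, sample metadata, results.

The analysis consumes three aligned objects: an :class:`AbundanceTable`
(samples x OTUs relative abundances), an optional :class:`PhyloTree` (rooted,
with branch lengths, leaves labelled by OTU ids), and a design extracted
from a :class:`SampleMetadata` table (variables of interest and confounders,
dummy-encoded and mean-centered).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "PhyloTree",
    "SampleMetadata",
    "read_abundance_table",
    "read_newick",
    "read_metadata",
    "align_inputs",
    "write_results",
]


class FormatError(ValueError):
    """Malformed input file."""


class DegenerateSampleError(ValueError):
    """A sample with zero total abundance cannot be normalized."""


class AlignmentError(ValueError):
    """Inputs share no samples (or OTU/leaf mapping failed)."""


@dataclass
class AbundanceTable:
    """n x K relative-abundance matrix with sample and OTU identifiers.

    Rows are compositions: each sums to one.  Construct from raw counts or
    proportions with :meth:`from_values`, which normalizes rows.
    """

    values: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if n < 3:
            raise FormatError("need at least 3 samples")
        if k < 2:
            raise FormatError("need at least 2 OTUs")
        if len(self.sample_ids) != n or len(self.otu_ids) != k:
            raise FormatError("identifier count does not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample identifiers")
        if len(set(self.otu_ids)) != k:
            raise FormatError("duplicate OTU identifiers")
        if not np.isfinite(self.values).all():
            raise FormatError("non-finite abundance values")
        if (self.values < 0).any():
            raise FormatError("negative abundance values")

    @classmethod
    def from_values(cls, values, sample_ids, otu_ids) -> "AbundanceTable":
        """Build a table from counts or proportions, normalizing each row."""
        values = np.asarray(values, dtype=float)
        totals = values.sum(axis=1)
        if (totals <= 0).any():
            bad = [sample_ids[i] for i in np.flatnonzero(totals <= 0)]
            raise DegenerateSampleError(f"zero-sum sample(s): {bad}")
        return cls(values / totals[:, None], list(sample_ids), list(otu_ids))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_otus(self) -> int:
        return self.values.shape[1]

    def select_samples(self, order: list[str]) -> "AbundanceTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in order]
        return AbundanceTable(self.values[idx], list(order), list(self.otu_ids))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)
        df.to_csv(path, sep="\t", float_format="%.17g", index_label="sample_id")


@dataclass
class PhyloTree:
    """Rooted phylogenetic tree with branch lengths, leaves naming OTUs."""

    tree: skbio.TreeNode
    leaf_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        tips = [t.name for t in self.tree.tips()]
        if any(t is None for t in tips):
            raise FormatError("unlabelled leaf in tree")
        if len(set(tips)) != len(tips):
            raise FormatError("leaf labels not unique")
        self.leaf_labels = tips
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                warnings.warn("missing branch length treated as 0", stacklevel=2)
                node.length = 0.0
            if not np.isfinite(node.length) or node.length < 0:
                raise FormatError("branch lengths must be finite and nonnegative")

    @property
    def n_branches(self) -> int:
        """Branches in deterministic postorder, root excluded."""
        return sum(1 for _ in self.tree.postorder(include_self=False))

    @property
    def total_length(self) -> float:
        return float(
            sum(n.length for n in self.tree.postorder(include_self=False))
        )

    def write_newick(self, path) -> None:
        self.tree.write(str(path), format="newick")


@dataclass
class SampleMetadata:
    """Per-sample covariate table keyed by sample identifier."""

    table: pd.DataFrame

    def __post_init__(self):
        if self.table.index.has_duplicates:
            raise FormatError("duplicate sample identifiers in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]


def read_abundance_table(
    path, orientation: str = "samples-as-rows"
) -> AbundanceTable:
    """Read a TSV abundance table (counts or proportions) and normalize rows."""
    if orientation not in ("samples-as-rows", "samples-as-cols"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise FormatError(f"cannot parse abundance table {path}: {exc}") from exc
    if orientation == "samples-as-cols":
        df = df.T
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        raise FormatError(f"non-numeric cell in abundance table {path}")
    return AbundanceTable.from_values(
        body.to_numpy(float), [str(s) for s in df.index], [str(o) for o in df.columns]
    )


def read_newick(path_or_str) -> PhyloTree:
    """Parse a Newick tree (file path or literal string)."""
    s = str(path_or_str)
    try:
        is_file = Path(s).exists()
    except OSError:
        is_file = False
    text = Path(s).read_text() if is_file else s
    if "(" not in text or ";" not in text:
        raise FormatError(f"not a Newick tree: {s[:80]!r}")
    try:
        tree = skbio.TreeNode.read(StringIO(text), format="newick")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unparseable Newick input: {exc}") from exc
    return PhyloTree(tree)


def read_metadata(path) -> SampleMetadata:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse metadata table {path}: {exc}") from exc
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def _encode_design(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    """Dummy-encode (one-hot minus reference) and mean-center design columns."""
    sub = df[cols]
    if sub.isna().any().any():
        raise FormatError(f"missing values in design columns {cols}")
    enc = pd.get_dummies(sub, drop_first=True, dtype=float)
    X = enc.to_numpy(float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    if (sd == 0).any():
        constant = [enc.columns[i] for i in np.flatnonzero(sd == 0)]
        warnings.warn(
            f"constant design column(s) after centering: {constant}", stacklevel=2
        )
    return X


def align_inputs(
    table: AbundanceTable,
    meta: SampleMetadata,
    x1_cols: list[str],
    x2_cols: list[str] | None = None,
    tree: PhyloTree | None = None,
):
    """Align table/metadata sample order and build centered design matrices.

    Returns ``(table, X1, X2, tree)`` with one common sample order (the
    table's, restricted to samples present in the metadata).  ``X2`` is None
    when no confounders are requested.  Samples missing from either input
    are dropped with a logged count.
    """
    meta_ids = set(meta.sample_ids)
    common = [s for s in table.sample_ids if s in meta_ids]
    if not common:
        raise AlignmentError("no samples shared between table and metadata")
    dropped = table.n_samples - len(common)
    if dropped:
        logger.info("dropped %d sample(s) missing from metadata", dropped)
    table = table.select_samples(common)
    df = meta.table.loc[common]
    X1 = _encode_design(df, list(x1_cols))
    X2 = _encode_design(df, list(x2_cols)) if x2_cols else None
    return table, X1, X2, tree


def _fmt(x: float) -> str:
    return f"{float(x):.17g}"


def write_results(result, out_dir) -> tuple[Path, Path]:
    """Write per-base-test TSV and a JSON ensemble summary.

    Output is byte-identical across repeated runs on identical input: the
    analysis path is deterministic and floats are serialized with a fixed
    repr-faithful format.
    """
    if not result.base:
        raise ValueError("empty base-result list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base_path = out_dir / "base_tests.tsv"
    cols = ["d", "r", "T", "E_p", "Var_p", "gamma_p", "pvalue"]
    lines = ["\t".join(cols)]
    for b in result.base:
        lines.append(
            "\t".join(
                [str(b.d), _fmt(b.r), _fmt(b.T), _fmt(b.E1), _fmt(b.Var),
                 _fmt(b.gamma), _fmt(b.pvalue)]
            )
        )
    base_path.write_text("\n".join(lines) + "\n")

    summary_path = out_dir / "summary.json"
    summary = {
        "T_ensemble": _fmt(result.T_ens),
        "P": _fmt(result.P),
        "D_set": [int(d) for d in result.D_set],
        "R_set": [float(r) for r in result.R_set],
        "n_base_tests": len(result.base),
    }
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return base_path, summary_path
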