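"""Reading, validation and harmonization of microbiome association inputs.

Four artifacts feed every analysis: an OTU count table (samples x OTUs),
a rooted phylogenetic tree with branch lengths whose tips cover the OTUs,
a Greengenes-style taxonomy lineage per OTU, and a study design holding the
outcome trait plus optional covariates.  This module parses each one,
enforces the invariants the statistics downstream rely on, and aligns them
into a single :class:`AlignedDataset`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("omiat")

#: The seven canonical taxonomic ranks, highest to lowest.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Greengenes rank prefixes, in rank order ("k__Bacteria; p__Firmicutes; ...").
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class InputError(ValueError):
    """Raised when an input artifact violates a structural invariant."""


# ---------------------------------------------------------------------------
# OTU count table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OtuTable:
    """Sample-by-OTU count matrix with identifier bookkeeping.

    Attributes
    ----------
    counts : ndarray of shape (n_samples, n_otus)
        Non-negative abundances.
    sample_ids : tuple of str
    otu_ids : tuple of str
    """

    counts: np.ndarray
    sample_ids: tuple
    otu_ids: tuple

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(str(o) for o in self.otu_ids))
        if counts.ndim != 2:
            raise InputError("counts must be a 2-D samples x OTUs matrix")
        n, p = counts.shape
        if n != len(self.sample_ids) or p != len(self.otu_ids):
            raise InputError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples / {len(self.otu_ids)} OTUs"
            )
        if n == 0 or p == 0:
            raise InputError("empty OTU table")
        if not np.all(np.isfinite(counts)):
            raise InputError("counts contain non-finite entries")
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise InputError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}"
            )
        for label, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            if len(set(ids)) != len(ids):
                seen, dup = set(), None
                for x in ids:
                    if x in seen:
                        dup = x
                        break
                    seen.add(x)
                raise InputError(f"duplicated {label} id {dup!r}")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.sample_ids),
                            columns=list(self.otu_ids))

    def select_otus(self, otu_ids) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        return OtuTable(self.counts[:, idx], self.sample_ids, tuple(otu_ids))

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(self.counts[idx], tuple(sample_ids), self.otu_ids)


def read_otu_table(path, format: str = "tsv", transpose: bool = False) -> OtuTable:
    """Read an OTU count table from TSV or BIOM.

    TSV orientation is rows = samples, columns = OTUs (header row of OTU
    ids, first column sample ids); pass ``transpose=True`` for the
    OTU-by-sample dialect.  BIOM tables (HDF5 or JSON) are always stored
    observation-by-sample and are transposed on load.
    """
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            dup = next(h for h in header if header.count(h) > 1)
            raise InputError(f"duplicated {'sample' if transpose else 'OTU'} "
                             f"id {dup!r} in header of {path}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        if transpose:
            df = df.T
        try:
            counts = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise InputError(f"non-numeric entries in OTU table {path}: {exc}")
        return OtuTable(counts, tuple(df.index.astype(str)),
                        tuple(df.columns.astype(str)))
    if format == "biom":
        return _read_biom(path)
    raise InputError(f"unknown OTU table format {format!r} (expected tsv or biom)")


def _read_biom(path) -> OtuTable:
    try:
        import biom

        table = biom.load_table(str(path))
        counts = np.asarray(table.matrix_data.todense()).T  # obs x sample -> sample x obs
        return OtuTable(counts, tuple(table.ids("sample")),
                        tuple(table.ids("observation")))
    except ImportError:
        pass
    # BIOM 1.0 is plain JSON: parse directly.
    with open(path) as fh:
        doc = json.load(fh)
    obs_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros(doc["shape"], dtype=float)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat[:] = doc["data"]
    return OtuTable(mat.T, tuple(sample_ids), tuple(obs_ids))


def write_otu_table_tsv(otu: OtuTable, path) -> None:
    otu.to_dataframe().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------

def read_tree(path, assume_unit_branch_lengths: bool = False) -> TreeNode:
    """Read a rooted Newick tree, validating branch lengths.

    Missing branch lengths are a hard error unless
    ``assume_unit_branch_lengths`` is set, in which case every edge gets
    length 1.  Distance measures depend on the lengths, so silently
    defaulting them would corrupt results.
    """
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree, assume_unit_branch_lengths)


def validate_tree(tree: TreeNode, assume_unit_branch_lengths: bool = False) -> TreeNode:
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if assume_unit_branch_lengths:
                node.length = 1.0
            else:
                raise InputError(
                    "tree has edges without branch lengths; pass "
                    "assume_unit_branch_lengths=True to use unit lengths"
                )
        elif node.length < 0:
            raise InputError(f"negative branch length at node {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise InputError("tree has duplicated tip labels")
    return tree


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

def parse_lineage(lineage: str) -> tuple:
    """Split a Greengenes-style lineage string into 7 rank labels.

    ``"k__Bacteria; p__Firmicutes; c__; ..."`` -> ("Bacteria", "Firmicutes",
    "", ...).  Empty labels after the prefix mean unassigned.  Missing
    trailing ranks are treated as unassigned.
    """
    fields = [f.strip() for f in str(lineage).split(";")]
    labels = []
    for i, prefix in enumerate(RANK_PREFIXES):
        if i < len(fields):
            f = fields[i]
            if f.startswith(prefix):
                f = f[len(prefix):]
            labels.append(f.strip())
        else:
            labels.append("")
    return tuple(labels)


def read_taxonomy(path) -> pd.DataFrame:
    """Read a two-column TSV (OTU id, lineage string) into a rank table.

    Returns a DataFrame indexed by OTU id with the 7 columns of
    :data:`RANKS`; unassigned labels are empty strings.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise InputError("taxonomy TSV needs at least two columns (otu id, lineage)")
    # tolerate a header row
    first = str(df.iloc[0, 1]).lower()
    if "taxon" in first or "lineage" in first:
        df = df.iloc[1:]
    otu_ids = df.iloc[:, 0].astype(str)
    if otu_ids.duplicated().any():
        dup = otu_ids[otu_ids.duplicated()].iloc[0]
        raise InputError(f"duplicated OTU id {dup!r} in taxonomy")
    rows = [parse_lineage(s) for s in df.iloc[:, 1]]
    return pd.DataFrame(rows, index=otu_ids.values, columns=list(RANKS))


def taxonomy_from_lineages(mapping: dict) -> pd.DataFrame:
    """Build a taxonomy table from {otu_id: lineage string}."""
    rows = {o: parse_lineage(s) for o, s in mapping.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Outcome trait and covariates for n samples.

    ``trait`` is ``"continuous"`` or ``"binary"``; binary outcomes must be
    coded 0/1 and contain both classes.  ``covariates`` has shape (n, q),
    possibly q = 0.
    """

    y: np.ndarray
    covariates: np.ndarray
    trait: str
    sample_ids: tuple = None

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        X = np.asarray(self.covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.size == 0:
            X = np.empty((y.shape[0], 0))
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "covariates", X)
        if self.trait not in ("continuous", "binary"):
            raise InputError("trait must be 'continuous' or 'binary'")
        if y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise InputError("outcome and covariates have mismatched lengths")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise InputError("non-finite values in outcome or covariates")
        if self.trait == "binary":
            if not np.isin(y, (0.0, 1.0)).all():
                raise InputError("binary outcome must be coded 0/1")
            if y.min() == y.max():
                raise InputError("binary outcome contains a single class")
        if self.sample_ids is not None:
            ids = tuple(str(s) for s in self.sample_ids)
            if len(ids) != y.shape[0]:
                raise InputError("sample_ids length does not match outcome")
            object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.y.shape[0]

    def select_samples(self, sample_ids) -> "StudyDesign":
        if self.sample_ids is None:
            raise InputError("design has no sample ids to align on")
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return StudyDesign(self.y[idx], self.covariates[idx], self.trait,
                           tuple(sample_ids))


def read_design(path, outcome_col: str, covariate_cols=(), trait: str = "continuous") -> StudyDesign:
    """Read the design TSV (first column sample ids) and pick columns by name."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if outcome_col not in df.columns:
        raise InputError(f"outcome column {outcome_col!r} not in design file")
    missing = [c for c in covariate_cols if c not in df.columns]
    if missing:
        raise InputError(f"covariate columns missing from design file: {missing}")
    X = df[list(covariate_cols)].to_numpy(dtype=float) if covariate_cols \
        else np.empty((len(df), 0))
    return StudyDesign(df[outcome_col].to_numpy(dtype=float), X, trait,
                       tuple(df.index.astype(str)))


# ---------------------------------------------------------------------------
# Harmonization and filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedDataset:
    """Counts, tree, taxonomy and design restricted to shared ids, in one order."""

    otu: OtuTable
    tree: TreeNode
    taxonomy: pd.DataFrame
    design: StudyDesign

    @property
    def otu_ids(self) -> tuple:
        return self.otu.otu_ids

    @property
    def sample_ids(self) -> tuple:
        return self.otu.sample_ids


def harmonize(otu: OtuTable, tree: TreeNode, taxonomy: pd.DataFrame,
              design: StudyDesign) -> AlignedDataset:
    """Align the four inputs on shared OTU and sample identifiers.

    The OTU set is restricted to the intersection of table, tree tips and
    taxonomy rows (tree tips may be a superset).  Samples follow the count
    table's order; the design must cover them.  Dropped ids are logged.
    """
    tip_names = {t.name for t in tree.tips()}
    tax_ids = set(taxonomy.index.astype(str))
    kept = [o for o in otu.otu_ids if o in tip_names and o in tax_ids]
    dropped = [o for o in otu.otu_ids if o not in kept]
    if dropped:
        logger.warning("harmonize: dropping %d OTU(s) absent from tree or "
                       "taxonomy: %s", len(dropped), ", ".join(dropped[:10]))
    if not kept:
        raise InputError("no OTUs shared by count table, tree and taxonomy")

    if design.sample_ids is not None:
        missing = [s for s in otu.sample_ids if s not in design.sample_ids]
        if missing:
            raise InputError(f"samples missing from design: {missing[:10]}")
        design = design.select_samples(otu.sample_ids)
    elif design.n_samples != otu.n_samples:
        raise InputError("design length does not match number of samples")

    out = otu.select_otus(kept) if dropped else otu
    totals = out.counts.sum(axis=1)
    if (totals == 0).any():
        keep_samples = [s for s, t in zip(out.sample_ids, totals) if t > 0]
        zeroed = [s for s, t in zip(out.sample_ids, totals) if t == 0]
        logger.warning("harmonize: dropping %d zero-total sample(s): %s",
                       len(zeroed), ", ".join(zeroed[:10]))
        if not keep_samples:
            raise InputError("all samples have zero total count")
        out = out.select_samples(keep_samples)
        design = design.select_samples(keep_samples) if design.sample_ids \
            else StudyDesign(design.y[totals > 0], design.covariates[totals > 0],
                             design.trait)
    sub_tax = taxonomy.loc[list(out.otu_ids)]
    sub_tree = tree.shear(list(out.otu_ids)) if tip_names - set(out.otu_ids) else tree
    if sub_tree.length is None:
        sub_tree.length = 0.0
    return AlignedDataset(out, sub_tree, sub_tax, design)


def filter_by_mean_proportion(otu: OtuTable, threshold: float = 1e-3) -> OtuTable:
    """Keep OTUs whose mean per-sample proportion exceeds ``threshold``.

    Proportions are computed per sample first, then averaged per OTU across
    samples; the comparison is strict (mean > threshold).  Samples whose
    total drops to zero afterwards are removed with a warning.
    """
    if not (0 <= threshold < 1):
        raise InputError("threshold must lie in [0, 1)")
    totals = otu.counts.sum(axis=1)
    if (totals == 0).any():
        raise InputError("zero-total sample in table; drop it before filtering")
    props = otu.counts / totals[:, None]
    keep = props.mean(axis=0) > threshold
    if not keep.any():
        raise InputError(f"no OTU has mean proportion > {threshold}")
    kept_ids = [o for o, k in zip(otu.otu_ids, keep) if k]
    out = otu.select_otus(kept_ids)
    new_totals = out.counts.sum(axis=1)
    if (new_totals == 0).any():
        keep_samples = [s for s, t in zip(out.sample_ids, new_totals) if t > 0]
        warnings.warn(f"dropping {out.n_samples - len(keep_samples)} sample(s) "
                      "with zero total after filtering")
        out = out.select_samples(keep_samples)
    return out
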