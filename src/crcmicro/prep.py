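"""Feature-table container, I/O, sample QC and the rare-species filter.

The central container is :class:`FeatureTable`, a thin wrapper around a
``pandas.DataFrame`` of samples x species with optional per-taxon lineage
strings.  Tables are either in ``counts`` mode (non-negative integers, the
raw sequencing output after annotation) or ``proportions`` mode (each row
sums to one).  All downstream stages consume this container.

Filtering follows the cohort pipeline conventions: samples below a minimum
library size are dropped first, then species that are rare both in
prevalence and in mean relative abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .errors import (
    DegenerateSampleError,
    EmptyResultError,
    FormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Minimum library size for a sample to enter the analyses.
DEFAULT_MIN_READS = 50_000
#: Minimum fraction of samples in which a species must be observed.
DEFAULT_MIN_PREVALENCE = 0.01
#: Minimum mean relative abundance of a species across samples.
DEFAULT_MIN_MEAN_RELABUND = 0.0001


@dataclass
class FeatureTable:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are taxa.  Non-negative.
    taxonomy : pandas.Series, optional
        Per-taxon lineage string (domain -> species), indexed by taxon id.
    mode : {"counts", "proportions"}
        Whether ``data`` holds raw read counts or relative abundances.
    """

    data: pd.DataFrame
    taxonomy: pd.Series | None = None
    mode: str = "counts"

    def __post_init__(self):
        if self.mode not in ("counts", "proportions"):
            raise ValidationError(f"unknown table mode {self.mode!r}")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate taxon ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric abundances")
        if np.any(values < 0) or np.any(~np.isfinite(values)):
            raise FormatError("negative or non-finite abundances")
        if self.mode == "proportions":
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValidationError("proportion rows must sum to 1")
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.data.columns)

    # -- basic views ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def library_sizes(self) -> pd.Series:
        """Row sums (total reads per sample in counts mode)."""
        return self.data.sum(axis=1)

    def copy(self) -> "FeatureTable":
        taxonomy = None if self.taxonomy is None else self.taxonomy.copy()
        return FeatureTable(self.data.copy(), taxonomy, self.mode)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(path, format: str = "tsv") -> FeatureTable:
    """Read a samples x taxa count table.

    The TSV dialect is: tab-separated, header row of taxon ids, first
    column the sample id.  An optional second header line starting with
    ``#taxonomy`` carries lineage strings (tab-separated, aligned with the
    taxon columns).
    """
    if format != "tsv":
        raise FormatError(
            f"unsupported format {format!r}: this build reads TSV tables"
        )
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        pos = fh.tell()
        second = fh.readline()
        taxonomy = None
        if second.startswith("#taxonomy"):
            lineages = second.rstrip("\n").split("\t")[1:]
            taxonomy = pd.Series(lineages, index=header[1:], name="taxonomy")
        else:
            fh.seek(pos)
        try:
            df = pd.read_csv(fh, sep="\t", header=None, names=header,
                             index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise FormatError(f"cannot parse {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric counts")
    if np.any(values != np.floor(values)):
        raise FormatError(f"{path}: counts must be integers")
    return FeatureTable(df.astype(np.int64), taxonomy, mode="counts")


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a table in the TSV dialect read by :func:`read_feature_table`."""
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(table.taxon_ids) + "\n")
        if table.taxonomy is not None and table.taxonomy.notna().any():
            fh.write("#taxonomy\t"
                     + "\t".join(str(x) for x in table.taxonomy.fillna(""))
                     + "\n")
        table.data.to_csv(fh, sep="\t", header=False)


def read_tree(path) -> skbio.TreeNode:
    """Read a rooted newick phylogeny (quoted labels tolerated)."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise FormatError("negative branch length in tree")
    return tree


# ---------------------------------------------------------------------------
# QC and transforms
# ---------------------------------------------------------------------------

def qc_filter_samples(table: FeatureTable,
                      min_reads: int = DEFAULT_MIN_READS) -> FeatureTable:
    """Drop samples whose library size is below ``min_reads`` (inclusive
    threshold: a sample with exactly ``min_reads`` reads is kept)."""
    if table.mode != "counts":
        raise ValidationError("sample QC requires a counts-mode table")
    sums = table.library_sizes()
    keep = sums >= min_reads
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.info("qc_filter_samples: dropping %d/%d samples below %d reads",
                    len(dropped), table.n_samples, min_reads)
    if not keep.any():
        raise EmptyResultError("all samples below the read-count threshold")
    return FeatureTable(table.data.loc[keep.to_numpy()],
                        table.taxonomy, "counts")


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Scale each sample's counts to its total read count."""
    if table.mode != "counts":
        raise ValidationError("relative_abundance expects a counts table")
    sums = table.data.sum(axis=1)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise DegenerateSampleError(f"zero-sum samples: {bad}")
    props = table.data.div(sums, axis=0)
    return FeatureTable(props, table.taxonomy, "proportions")


def filter_rare_species(
    table: FeatureTable,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    min_mean_relabund: float = DEFAULT_MIN_MEAN_RELABUND,
) -> FeatureTable:
    """Drop species with prevalence below ``min_prevalence`` or mean
    relative abundance below ``min_mean_relabund``.

    Prevalence is the fraction of samples with a strictly positive raw
    count.  Mean relative abundance is computed on the per-sample
    proportions.  The filter is idempotent.
    """
    for name, thr in (("min_prevalence", min_prevalence),
                      ("min_mean_relabund", min_mean_relabund)):
        if not 0 <= thr <= 1:
            raise ValidationError(f"{name} must lie in [0, 1]")
    if table.mode != "counts":
        raise ValidationError("rare-species filter expects a counts table")
    counts = table.data.to_numpy()
    prevalence = (counts > 0).mean(axis=0)
    props = relative_abundance(table).data.to_numpy()
    mean_relabund = props.mean(axis=0)
    keep = (prevalence >= min_prevalence) & (mean_relabund >= min_mean_relabund)
    dropped = [t for t, k in zip(table.taxon_ids, keep) if not k]
    if dropped:
        logger.info("filter_rare_species: dropping %d/%d taxa",
                    len(dropped), table.n_taxa)
    if not keep.any():
        raise EmptyResultError("all taxa removed by the rare-species filter")
    out = FeatureTable(table.data.loc[:, keep], table.taxonomy, "counts")
    out.dropped_taxa = dropped
    return out
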