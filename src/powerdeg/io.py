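"""Reading and writing the package's plain-text formats.

Counts are genes x samples integer TSV (first column the gene id); sample
metadata is a TSV with columns ``sample``, ``genotype``, ``sex``, ``group``
and optionally ``size_factor``; gene-set annotations are GMT or two-column
(gene, term) TSV; bias covariates are two-column (gene, value) TSV.  Lines
starting with ``#`` are provenance comments and are ignored on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


GENOTYPES = ("KO", "WT")


@dataclass
class CountMatrix:
    """Gene-by-sample fragment counts with sample metadata.

    ``counts`` is a genes x samples DataFrame of non-negative integers;
    ``meta`` is indexed by sample id with at least a ``genotype`` column
    (values ``KO``/``WT``), plus ``sex`` (``F``/``M``/``NA``), ``group`` and
    ``size_factor`` when known.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self):
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise FormatError(f"duplicated gene id {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise FormatError(f"duplicated sample id {dup!r}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.floor(vals)):
                bad = c.index[np.where(vals != np.floor(vals))[0][0]]
                raise FormatError(f"non-integer count in gene {bad!r}")
            self.counts = c = c.astype(np.int64)
            vals = c.to_numpy()
        if (vals < 0).any():
            bad = c.index[np.where((vals < 0).any(axis=1))[0][0]]
            raise FormatError(f"negative count in gene {bad!r}")
        missing = set(c.columns) - set(self.meta.index)
        if missing:
            raise FormatError(f"metadata missing sample {sorted(missing)[0]!r}")
        if "genotype" not in self.meta.columns:
            raise FormatError("metadata lacks a 'genotype' column")
        bad_gt = set(self.meta.loc[list(c.columns), "genotype"]) - set(GENOTYPES)
        if bad_gt:
            raise FormatError(f"unknown genotype label {sorted(bad_gt)[0]!r}")
        # align metadata to column order
        self.meta = self.meta.loc[list(c.columns)]

    @property
    def genes(self):
        return list(self.counts.index)

    @property
    def samples(self):
        return list(self.counts.columns)

    def samples_of(self, genotype: str) -> list[str]:
        return list(self.meta.index[self.meta["genotype"] == genotype])

    def subset_samples(self, samples) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix(self.counts[samples].copy(), self.meta.loc[samples].copy())

    def with_counts(self, counts: np.ndarray) -> "CountMatrix":
        new = pd.DataFrame(
            counts, index=self.counts.index, columns=self.counts.columns
        )
        return CountMatrix(new, self.meta.copy())

    def __eq__(self, other):
        return (
            isinstance(other, CountMatrix)
            and self.counts.equals(other.counts)
            and self.meta.equals(other.meta)
        )


def write_counts(cm: CountMatrix, counts_path, meta_path=None, comments=()):
    """Write counts (and optionally metadata) as TSV."""
    with open(counts_path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        cm.counts.rename_axis("gene_id").to_csv(fh, sep="\t")
    if meta_path is not None:
        write_metadata(cm.meta, meta_path, comments=comments)


def write_metadata(meta: pd.DataFrame, path, comments=()):
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        meta.rename_axis("sample").to_csv(fh, sep="\t")


def read_counts(counts_path, meta_path=None) -> CountMatrix:
    """Read a counts TSV (+ metadata TSV) back into a :class:`CountMatrix`."""
    try:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # noqa: BLE001 - rewrap as format error
        raise FormatError(f"cannot parse counts file {counts_path}: {exc}") from exc
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    bad = [c for c, dt in counts.dtypes.items() if not np.issubdtype(dt, np.number)]
    if bad:
        raise FormatError(
            f"{counts_path}: non-numeric counts in column {bad[0]!r}"
        )
    if meta_path is not None:
        meta = read_metadata(meta_path)
    else:
        meta = pd.DataFrame(
            {"genotype": ["WT"] * counts.shape[1]}, index=counts.columns
        )
    return CountMatrix(counts, meta)


def read_metadata(path) -> pd.DataFrame:
    # keep_default_na off: "NA" is a legitimate sex/group label, not missing
    meta = pd.read_csv(
        path, sep="\t", index_col=0, comment="#", dtype=str, keep_default_na=False
    )
    meta.index = meta.index.astype(str)
    if "size_factor" in meta.columns:
        meta["size_factor"] = meta["size_factor"].astype(float)
    return meta


def write_counts_mtx(cm: CountMatrix, prefix):
    """Write counts in MatrixMarket triplet form with id side-car files."""
    from scipy import io as spio
    from scipy import sparse

    spio.mmwrite(f"{prefix}.mtx", sparse.coo_matrix(cm.counts.to_numpy()))
    pd.Series(cm.genes).to_csv(f"{prefix}.genes.tsv", sep="\t", index=False, header=False)
    write_metadata(cm.meta, f"{prefix}.samples.tsv")


def read_counts_mtx(prefix) -> CountMatrix:
    from scipy import io as spio

    mat = spio.mmread(f"{prefix}.mtx")
    genes = pd.read_csv(f"{prefix}.genes.tsv", sep="\t", header=None)[0].astype(str)
    meta = read_metadata(f"{prefix}.samples.tsv")
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    if not np.all(dense == np.floor(dense)):
        raise FormatError(f"non-integer count in {prefix}.mtx")
    counts = pd.DataFrame(
        dense.astype(np.int64), index=list(genes), columns=list(meta.index)
    )
    return CountMatrix(counts, meta)


@dataclass
class TermAnnotation:
    """Flat gene-set annotation with an optional per-gene bias covariate."""

    terms: dict = field(default_factory=dict)  # term id -> set of gene ids
    bias: dict = field(default_factory=dict)  # gene id -> positive real
    descriptions: dict = field(default_factory=dict)

    def genes(self) -> set:
        out = set()
        for members in self.terms.values():
            out |= members
        return out


def read_gmt(path) -> TermAnnotation:
    """Parse a GMT file (term, description, then member genes per line)."""
    terms, desc = {}, {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has < 3 fields")
            term, description, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if term in terms:
                raise FormatError(f"{path}:{lineno}: duplicated term {term!r}")
            terms[term] = set(genes)
            desc[term] = description
    return TermAnnotation(terms=terms, descriptions=desc)


def write_gmt(annotation: TermAnnotation, path):
    with open(path, "w") as fh:
        for term, members in annotation.terms.items():
            desc = annotation.descriptions.get(term, "")
            fh.write("\t".join([term, desc] + sorted(members)) + "\n")


def read_gene_term_tsv(path) -> TermAnnotation:
    """Two-column (gene, term) TSV to a :class:`TermAnnotation`."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene", "term"])
    terms: dict[str, set] = {}
    for gene, term in zip(df["gene"].astype(str), df["term"].astype(str)):
        terms.setdefault(term, set()).add(gene)
    return TermAnnotation(terms=terms)


def read_bias_tsv(path) -> dict:
    """Two-column (gene, covariate) TSV; covariates must be positive."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene", "bias"])
    bias = {}
    for i, (gene, val) in enumerate(zip(df["gene"].astype(str), df["bias"]), start=1):
        val = float(val)
        if not (np.isfinite(val) and val > 0):
            raise FormatError(f"{path}: row {i}: bias covariate must be positive")
        bias[gene] = val
    return bias


def write_degs(degset, path, comments=()):
    """DEG set as two-column (gene, direction) TSV."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("gene\tdirection\n")
        for gene, direction in sorted(degset.members):
            fh.write(f"{gene}\t{direction}\n")


def read_degs(path, analysis_id=None):
    from .de import DEGSet

    df = pd.read_csv(path, sep="\t", comment="#")
    members = frozenset(
        (str(g), str(d)) for g, d in zip(df["gene"], df["direction"])
    )
    return DEGSet(
        analysis_id=analysis_id or os.path.basename(str(path)), members=members
    )
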