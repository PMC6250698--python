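"""Feature tables: filters, rarefaction, taxonomy collapse, mitotypes.

The central container is :class:`FeatureTable`: an integer count matrix
(features x samples, the classic OTU-table orientation) plus per-sample
metadata and per-feature taxonomy.  Operations are plain functions that
return new tables; nothing mutates in place.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "VariantSet",
    "RANKS",
    "UNKNOWN",
    "filter_samples_by_depth",
    "rarefy",
    "collapse_taxonomy",
    "purge_rare_features",
    "prevalence",
    "core_features",
    "dereplicate_variants",
    "filter_variants_by_total",
    "set_host_flags",
    "assign_mitotype",
    "read_table_tsv",
    "read_metadata_tsv",
    "read_biom_json",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: sentinel for missing metadata; never treated as a factor level
UNKNOWN = "Unknown"


@dataclass
class FeatureTable:
    """Counts (features x samples) with sample metadata and taxonomy.

    Invariants enforced at construction: integer counts >= 0, unique
    sample/feature ids, metadata indexed by the sample ids (missing cells
    filled with the ``Unknown`` sentinel).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = None
    taxonomy: pd.Series = None

    def __post_init__(self):
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.values.dtype, np.integer):
            vals = counts.values
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.counts = counts
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=counts.columns)
        else:
            missing = counts.columns.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"metadata missing for samples: "
                                 f"{sorted(missing)[:5]}")
            self.metadata = (self.metadata.reindex(counts.columns)
                             .fillna(UNKNOWN))
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(counts.index).fillna("")

    # -- convenience -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def feature_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    def select_samples(self, sample_ids) -> "FeatureTable":
        sample_ids = list(sample_ids)
        return FeatureTable(self.counts[sample_ids],
                            self.metadata.loc[sample_ids], self.taxonomy)

    def select_features(self, feature_ids) -> "FeatureTable":
        feature_ids = list(feature_ids)
        tax = (self.taxonomy.loc[feature_ids]
               if self.taxonomy is not None else None)
        return FeatureTable(self.counts.loc[feature_ids],
                            self.metadata, tax)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "#OTU ID"
        out.to_csv(path, sep="\t")


def filter_samples_by_depth(t: FeatureTable, min_total: int) -> FeatureTable:
    """Keep samples whose total count is strictly greater than ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = t.sample_totals() > min_total
    return t.select_samples(t.counts.columns[keep])


def rarefy(t: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped.  Sampling is
    multivariate hypergeometric per sample and deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = t.sample_totals()
    keep = [s for s in t.sample_ids if totals[s] >= depth]
    cols = {}
    for s in keep:
        col = t.counts[s].to_numpy()
        if totals[s] == depth:
            cols[s] = col
        else:
            cols[s] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(cols, index=t.counts.index, dtype=np.int64)
    if not keep:
        counts = t.counts.iloc[:, :0]
    return FeatureTable(counts, t.metadata.loc[keep], t.taxonomy)


def _lineage_levels(lineage: str) -> list[str]:
    parts = [p.strip() for p in str(lineage).split(";")]
    # strip QIIME-style rank prefixes like "g__"
    out = []
    for p in parts:
        if len(p) >= 3 and p[1:3] == "__":
            p = p[3:]
        out.append(p)
    return out


def collapse_taxonomy(t: FeatureTable, rank: str) -> FeatureTable:
    """Sum features sharing the same lineage prefix through ``rank``.

    Features unannotated at ``rank`` pool under
    ``"unclassified <deepest annotated ancestor>"``.  The grand total is
    conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if t.taxonomy is None:
        raise ValueError("table has no taxonomy to collapse")
    depth = RANKS.index(rank)
    labels = []
    for fid in t.feature_ids:
        levels = _lineage_levels(t.taxonomy.loc[fid])
        levels = levels + [""] * (len(RANKS) - len(levels))
        if levels[depth]:
            labels.append(";".join(levels[: depth + 1]))
        else:
            annotated = [l for l in levels[:depth] if l]
            anc = annotated[-1] if annotated else "Root"
            labels.append(f"unclassified {anc}")
    counts = t.counts.groupby(pd.Index(labels, name="taxon"), sort=True).sum()
    tax = pd.Series(counts.index, index=counts.index)
    return FeatureTable(counts, t.metadata, tax)


def purge_rare_features(t: FeatureTable, rel_cut: float) -> FeatureTable:
    """Drop features with total count < ``rel_cut`` x grand total."""
    if not 0 <= rel_cut < 1:
        raise ValueError("rel_cut must be in [0, 1)")
    cutoff = rel_cut * t.grand_total()
    keep = t.feature_totals() >= cutoff
    return t.select_features(t.counts.index[keep])


def prevalence(t: FeatureTable, group_by: str | None = None) -> pd.DataFrame:
    """Fraction of samples (optionally within metadata groups) where each
    feature has count > 0.  Returns a features x groups frame (single
    column ``all`` when ungrouped).  ``Unknown`` metadata values form no
    group."""
    if t.counts.shape[1] == 0:
        raise ValueError("prevalence of an empty table is undefined")
    present = t.counts > 0
    if group_by is None:
        return pd.DataFrame({"all": present.mean(axis=1)})
    if group_by not in t.metadata.columns:
        raise KeyError(f"unknown metadata key {group_by!r}")
    groups = t.metadata[group_by]
    out = {}
    for g, idx in groups.groupby(groups).groups.items():
        if g == UNKNOWN:
            continue
        out[g] = present[list(idx)].mean(axis=1)
    return pd.DataFrame(out)


def core_features(t: FeatureTable, threshold: float = 0.5,
                  group_by: str | None = None) -> set[str]:
    """Features whose prevalence strictly exceeds ``threshold`` in at
    least one group."""
    prev = prevalence(t, group_by)
    mask = (prev > threshold).any(axis=1)
    return set(prev.index[mask])


# -- sequence variants and mitotypes ------------------------------------


@dataclass
class VariantSet:
    """Dereplicated exact sequence variants with per-sample counts."""

    sequences: dict = field(default_factory=dict)      # id -> sequence
    counts: dict = field(default_factory=dict)         # id -> {sample: n}
    host_flags: dict = field(default_factory=dict)     # id -> bool

    def total(self, vid: str) -> int:
        return sum(self.counts[vid].values())

    def totals(self) -> dict:
        return {vid: self.total(vid) for vid in self.sequences}

    @property
    def variant_ids(self) -> list[str]:
        return list(self.sequences)


def dereplicate_variants(per_sample_sequences: dict) -> VariantSet:
    """Collapse 100%-identical sequences across samples.

    ``per_sample_sequences`` maps sample id to an iterable of sequences
    (upper/lower case are identical).  Variant ids are assigned in order of
    decreasing total count, ties broken by sequence, as ``v000001`` etc.
    """
    seq_counts: dict[str, dict[str, int]] = {}
    for sample, seqs in per_sample_sequences.items():
        for seq in seqs:
            seq = seq.upper()
            per = seq_counts.setdefault(seq, {})
            per[sample] = per.get(sample, 0) + 1
    order = sorted(seq_counts,
                   key=lambda s: (-sum(seq_counts[s].values()), s))
    vs = VariantSet()
    for i, seq in enumerate(order, start=1):
        vid = f"v{i:06d}"
        vs.sequences[vid] = seq
        vs.counts[vid] = dict(seq_counts[seq])
        vs.host_flags[vid] = False
    return vs


def filter_variants_by_total(v: VariantSet, min_total: int = 100) -> VariantSet:
    """Keep variants whose total count is at least ``min_total`` (inclusive)."""
    keep = [vid for vid in v.variant_ids if v.total(vid) >= min_total]
    return VariantSet({k: v.sequences[k] for k in keep},
                      {k: dict(v.counts[k]) for k in keep},
                      {k: v.host_flags[k] for k in keep})


def set_host_flags(v: VariantSet, classifier) -> VariantSet:
    """Flag host (mitochondrial) variants using a supplied classifier.

    ``classifier`` is any callable mapping a sequence string to bool; it
    stands in for an external homology search against a reference database.
    """
    for vid, seq in v.sequences.items():
        v.host_flags[vid] = bool(classifier(seq))
    return v


def assign_mitotype(v: VariantSet, sample_id: str) -> str | None:
    """Most abundant host-flagged variant in a sample (its mitotype).

    Ties break to the lexicographically smallest variant id; returns None
    when the sample contains no host-flagged variant.
    """
    if not any(sample_id in c for c in v.counts.values()):
        raise KeyError(f"unknown sample id {sample_id!r}")
    best = None
    for vid in sorted(v.variant_ids):
        if not v.host_flags[vid]:
            continue
        n = v.counts[vid].get(sample_id, 0)
        if n > 0 and (best is None or n > best[0]):
            best = (n, vid)
    return None if best is None else best[1]


# -- I/O -----------------------------------------------------------------


def read_table_tsv(path, taxonomy_column: str = "taxonomy") -> FeatureTable:
    """Read a classic features-x-samples TSV table.

    The first column holds feature ids; an optional trailing ``taxonomy``
    column holds semicolon-delimited lineages.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    if df.index.name and df.index.name.startswith("#"):
        df.index.name = df.index.name.lstrip("# ")
    tax = None
    if taxonomy_column in df.columns:
        tax = df[taxonomy_column].astype(str)
        df = df.drop(columns=[taxonomy_column])
    return FeatureTable(df.astype(np.int64), taxonomy=tax)


def read_metadata_tsv(path) -> pd.DataFrame:
    """Read a QIIME-style mapping file (first column = sample id)."""
    md = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if md.index.name and md.index.name.startswith("#"):
        md.index.name = md.index.name.lstrip("# ")
    return md.fillna(UNKNOWN)


def read_biom_json(path) -> FeatureTable:
    """Read a BIOM 1.0 (JSON) table, dense or sparse."""
    with open(path) as fh:
        doc = json.load(fh)
    fids = [r["id"] for r in doc["rows"]]
    sids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(fids), len(sids)), dtype=np.int64)
    if doc.get("matrix_type") == "sparse":
        for i, j, val in doc["data"]:
            mat[int(i), int(j)] = int(val)
    else:
        mat[:] = np.asarray(doc["data"], dtype=np.int64)
    tax = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        lineage = md.get("taxonomy", "")
        if isinstance(lineage, (list, tuple)):
            lineage = ";".join(lineage)
        tax[r["id"]] = lineage
    counts = pd.DataFrame(mat, index=fids, columns=sids)
    return FeatureTable(counts, taxonomy=pd.Series(tax))
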