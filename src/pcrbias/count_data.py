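"""Count tables, sample metadata, preprocessing filters and variant mapping.

Tables are oriented taxa x samples (rows = taxa, columns = samples) to match
the indexing of the bias model: sample i carries covariates, taxon j carries
an amplification efficiency. Zeros are legitimate count observations and are
never imputed here; the model handles them through the multinomial likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "SampleMetadata",
    "read_counts",
    "write_counts",
    "read_metadata",
    "filter_min_reads",
    "amalgamate_rare",
    "map_variants",
]


@dataclass(frozen=True)
class CountTable:
    """Taxa-by-sample matrix of nonnegative integer read counts."""

    counts: np.ndarray  # (D, N) integers
    taxa: tuple[str, ...]
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D taxa x samples matrix")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "taxa", tuple(str(t) for t in self.taxa))
        object.__setattr__(self, "samples", tuple(str(s) for s in self.samples))
        D, N = counts.shape
        if D < 2:
            raise ValueError("need at least two taxa")
        # N == 0 is legal (e.g. after filtering); the model itself needs N >= 1
        if len(self.taxa) != D or len(self.samples) != N:
            raise ValueError("label lengths must match matrix shape")
        if len(set(self.taxa)) != D:
            raise ValueError("duplicate taxon identifiers")
        if len(set(self.samples)) != N:
            raise ValueError("duplicate sample identifiers")

    @property
    def D(self) -> int:
        return self.counts.shape[0]

    @property
    def N(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.taxa), columns=list(self.samples))

    def select_samples(self, keep: list[str]) -> "CountTable":
        idx = [self.samples.index(s) for s in keep]
        return CountTable(self.counts[:, idx], self.taxa, keep)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample covariates: PCR cycle number, group label, machine/batch."""

    table: pd.DataFrame  # index = sample_id; columns cycle, group, batch

    def __post_init__(self) -> None:
        required = {"cycle", "group", "batch"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in metadata")
        cyc = self.table["cycle"].dropna()
        if (cyc < 0).any():
            raise ValueError("cycle numbers must be >= 0")

    def for_samples(self, samples: tuple[str, ...]) -> pd.DataFrame:
        missing = [s for s in samples if s not in self.table.index]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing}")
        return self.table.loc[list(samples)]


def read_counts(path: str | Path, *, sep: str | None = None, transpose: bool = False) -> CountTable:
    """Read a taxa x samples count table from TSV/CSV.

    First column holds taxon identifiers, header row holds sample identifiers.
    Set ``transpose=True`` for tables stored samples x taxa.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    # check the raw header: pandas silently renames duplicated columns
    header = path.read_text().splitlines()[0].split(sep)[1:]
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:
        raise ValueError(f"duplicate sample identifiers in {path}: {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon identifiers in {path}: {dups}")
    values = df.to_numpy()
    for (r, c), v in np.ndenumerate(values):
        try:
            fv = float(v)
            ok = fv.is_integer() and fv >= 0
        except (TypeError, ValueError):
            ok = False
        if not ok:
            raise ValueError(
                f"non-(nonnegative-integer) count at taxon {df.index[r]!r}, "
                f"sample {df.columns[c]!r}: {v!r}"
            )
    return CountTable(values.astype(np.int64), tuple(df.index.astype(str)), tuple(df.columns.astype(str)))


def write_counts(table: CountTable, path: str | Path, *, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.to_frame().to_csv(path, sep=sep, index_label="taxon")


def read_metadata(path: str | Path, *, sep: str | None = None) -> SampleMetadata:
    """Read per-sample metadata (columns sample_id, cycle, group, batch)."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"group": str, "batch": str})
    if "sample_id" not in df.columns:
        raise ValueError("metadata must have a sample_id column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path, *, sep: str = "\t") -> None:
    meta.table.to_csv(path, sep=sep, index_label="sample_id")


def filter_min_reads(table: CountTable, threshold: int = 1000) -> CountTable:
    """Keep samples with column sum strictly greater than ``threshold`` reads.

    The cut is strict ("more than"): a sample with exactly ``threshold`` reads
    is dropped. Taxa are unchanged.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sums = table.counts.sum(axis=0)
    keep = sums > threshold
    total = table.counts.sum()
    retained = table.counts[:, keep].sum()
    frac = retained / total if total else float("nan")
    logger.info(
        "read filter >%d: kept %d/%d samples, %.4f of counts",
        threshold, int(keep.sum()), table.N, frac,
    )
    if not keep.any():
        warnings.warn(f"no samples exceed {threshold} reads; result is empty", stacklevel=2)
        return CountTable(
            np.zeros((table.D, 0), dtype=np.int64), table.taxa, ())
    kept_samples = tuple(s for s, k in zip(table.samples, keep) if k)
    return CountTable(table.counts[:, keep], table.taxa, kept_samples)


def amalgamate_rare(
    table: CountTable,
    prevalence: float = 0.30,
    min_count: int = 3,
    label: str = "other",
) -> CountTable:
    """Collapse rare taxa into a single pooled row.

    A taxon is kept iff it has at least ``min_count`` reads in at least a
    ``prevalence`` fraction of samples (both thresholds inclusive). All other
    taxa are summed into one row named ``label``. Per-sample totals are
    conserved exactly.
    """
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    seen = (table.counts >= min_count).sum(axis=1)
    keep = seen / table.N >= prevalence
    if keep.all():
        return table
    if not keep.any():
        raise ValueError("all taxa are rare; the model needs at least two taxa")
    if label in [t for t, k in zip(table.taxa, keep) if k]:
        raise ValueError(f"amalgamation label {label!r} collides with a kept taxon")
    pooled = table.counts[~keep].sum(axis=0)
    counts = np.vstack([table.counts[keep], pooled])
    taxa = tuple(t for t, k in zip(table.taxa, keep) if k) + (label,)
    logger.info("amalgamated %d rare taxa into %r", int((~keep).sum()), label)
    return CountTable(counts, taxa, table.samples)


_DNA = set("ACGTN")


def map_variants(
    query_seqs: dict[str, str], ref_seqs: dict[str, str]
) -> pd.DataFrame:
    """Assign each query sequence to its nearest reference by edit distance.

    Returns a frame indexed by query id with columns ``reference`` (the
    minimum-Levenshtein reference, or a comma-joined list on ties),
    ``distance`` and ``tie``. Ties are reported, never silently broken.
    """
    if not ref_seqs:
        raise ValueError("reference set must be nonempty")
    if not query_seqs:
        raise ValueError("query set must be nonempty")
    for name, seq in list(query_seqs.items()) + list(ref_seqs.items()):
        if not seq or set(seq.upper()) - _DNA:
            raise ValueError(f"sequence {name!r} is empty or not over A/C/G/T/N")
    rows = []
    for qname, qseq in query_seqs.items():
        dists = {
            rname: edlib.align(qseq.upper(), rseq.upper(), task="distance")["editDistance"]
            for rname, rseq in ref_seqs.items()
        }
        dmin = min(dists.values())
        best = sorted(r for r, d in dists.items() if d == dmin)
        rows.append(
            {
                "query": qname,
                "reference": ",".join(best),
                "distance": dmin,
                "tie": len(best) > 1,
            }
        )
    return pd.DataFrame(rows).set_index("query")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {id: sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
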