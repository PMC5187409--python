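"""Pooled shRNA screen deconvolution and gene hit calling.

Half-hairpin amplicon reads carry the 21-nt shRNA identifier immediately
after a fixed 5-nt prefix and before a fixed 24-nt vector sequence:

    [read start] TCGAG [21 bp variable insert] CCGGTGTTTCGTCCTTTCCACAAG ...

A read is accepted only when this 50-nt pattern matches exactly and every
base call in it has Phred quality >= 35. Accepted inserts are mapped to the
shRNA library flatfile by exact sequence match (21-mers at Q>=35 are near
error-free; a 1-mismatch-tolerant mode is available behind a flag) and
counted per shRNA and replicate. A gene is significant in one replicate when
at least 3 of its shRNAs reach at least 500 reads, and is called a hit only
when significant in both replicate experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "READ_PREFIX",
    "VECTOR_SUFFIX",
    "Library",
    "ScreenCounts",
    "read_library",
    "extract_insert",
    "parse_fastq",
    "extract_inserts_from_fastq",
    "count_inserts",
    "call_hits",
]

READ_PREFIX = "TCGAG"
VECTOR_SUFFIX = "CCGGTGTTTCGTCCTTTCCACAAG"
INSERT_LEN = 21
PATTERN_LEN = len(READ_PREFIX) + INSERT_LEN + len(VECTOR_SUFFIX)  # 50 nt
MIN_QUALITY = 35


@dataclass
class Library:
    """shRNA library flatfile: one record per hairpin.

    ``records`` has columns (shrna_id, gene, sequence21); ids must be unique
    and sequences exactly 21 nt of uppercase ACGT.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"shrna_id", "gene", "sequence21"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"library needs columns {sorted(req)}")
        if self.records["shrna_id"].duplicated().any():
            raise ValueError("duplicate shrna_id in library")
        seqs = self.records["sequence21"]
        bad = ~seqs.str.fullmatch(r"[ACGT]{21}")
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} library sequences are not 21-nt uppercase ACGT"
            )

    @property
    def by_sequence(self) -> dict:
        return dict(zip(self.records["sequence21"], self.records["shrna_id"]))

    @property
    def genes(self) -> pd.Series:
        return self.records.set_index("shrna_id")["gene"]


def read_library(path: str | Path) -> Library:
    """Read a TSV flatfile with columns shrna_id, gene, sequence21."""
    return Library(pd.read_csv(path, sep="\t", dtype=str))


@dataclass
class ScreenCounts:
    """Per-shRNA read counts per replicate.

    ``counts``: DataFrame indexed by shrna_id with one integer column per
    replicate. ``unmapped``: accepted-but-unmatched insert count per
    replicate. ``rejected``: reads failing the pattern/quality filter.
    """

    counts: pd.DataFrame
    unmapped: dict
    rejected: dict


def extract_insert(
    read_sequence: str, read_qualities, min_quality: int = MIN_QUALITY
) -> str | None:
    """Return the 21-nt insert of one read, or None if the read is rejected.

    Acceptance requires: length >= 50; the read starts with TCGAG; bases
    27–50 equal the fixed vector sequence; and every base in the first 50 nt
    has quality >= ``min_quality``. Qualities may be a Phred+33 string or a
    sequence of integers.
    """
    if len(read_sequence) < PATTERN_LEN:
        return None
    if not read_sequence.startswith(READ_PREFIX):
        return None
    if read_sequence[INSERT_LEN + len(READ_PREFIX) : PATTERN_LEN] != VECTOR_SUFFIX:
        return None
    if isinstance(read_qualities, str):
        quals = [ord(c) - 33 for c in read_qualities[:PATTERN_LEN]]
    else:
        quals = list(read_qualities[:PATTERN_LEN])
    if len(quals) < PATTERN_LEN or min(quals) < min_quality:
        return None
    return read_sequence[len(READ_PREFIX) : len(READ_PREFIX) + INSERT_LEN]


def parse_fastq(path: str | Path):
    """Yield (read_id, sequence, quality_string) from a Phred+33 FASTQ file."""
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def extract_inserts_from_fastq(
    path: str | Path, min_quality: int = MIN_QUALITY
) -> tuple[list[str], int]:
    """Extract accepted inserts from a FASTQ file; returns (inserts, n_rejected)."""
    inserts, rejected = [], 0
    for _rid, seq, qual in parse_fastq(path):
        ins = extract_insert(seq, qual, min_quality)
        if ins is None:
            rejected += 1
        else:
            inserts.append(ins)
    return inserts, rejected


def _neighbours(seq: str):
    for i, base in enumerate(seq):
        for alt in "ACGT":
            if alt != base:
                yield seq[:i] + alt + seq[i + 1 :]


def count_inserts(
    inserts_by_replicate: dict,
    library: Library,
    allow_one_mismatch: bool = False,
    rejected_by_replicate: dict | None = None,
) -> ScreenCounts:
    """Map accepted inserts to the library and count reads per shRNA.

    Mapping is exact by default; with ``allow_one_mismatch`` an insert that
    fails exact lookup is matched to a library sequence at Hamming distance 1
    when that match is unique. Unmatched inserts are tallied as unmapped, so
    mapped + unmapped equals the number of accepted reads per replicate.
    """
    lookup = library.by_sequence
    if len(lookup) != len(library.records):
        raise ValueError("duplicate 21-mer sequences in library")
    replicates = list(inserts_by_replicate)
    counts = pd.DataFrame(
        0, index=library.records["shrna_id"].to_numpy(), columns=replicates, dtype=int
    )
    counts.index.name = "shrna_id"
    unmapped = {}
    for rep, inserts in inserts_by_replicate.items():
        miss = 0
        for ins in inserts:
            sid = lookup.get(ins)
            if sid is None and allow_one_mismatch:
                hits = {lookup[nb] for nb in _neighbours(ins) if nb in lookup}
                sid = hits.pop() if len(hits) == 1 else None
            if sid is None:
                miss += 1
            else:
                counts.at[sid, rep] += 1
        unmapped[rep] = miss
    return ScreenCounts(counts, unmapped, dict(rejected_by_replicate or {}))


def call_hits(
    counts: ScreenCounts | pd.DataFrame,
    library: Library,
    min_reads: int = 500,
    min_shrnas: int = 3,
) -> pd.DataFrame:
    """Apply the gene hit rule to a two-replicate count table.

    A gene is significant in a replicate when >= ``min_shrnas`` of its
    shRNAs have >= ``min_reads`` reads there; it is a hit only when
    significant in both replicates. Returns one row per gene, sorted by gene
    symbol, with columns n_ge_threshold_<rep>, significant_<rep>, is_hit.
    Genes present in the count table but with no library shRNAs are excluded
    with a warning.
    """
    table = counts.counts if isinstance(counts, ScreenCounts) else counts
    if table.shape[1] != 2:
        raise ValueError("hit calling requires exactly 2 replicate experiments")
    replicates = list(table.columns)
    genes = library.genes
    known = table.index.isin(genes.index)
    if not known.all():
        warnings.warn(
            f"{int((~known).sum())} shRNA ids missing from the library were excluded"
        )
        table = table.loc[known]
    gene_of = genes.loc[table.index]

    over = (table >= min_reads).groupby(gene_of.to_numpy()).sum()
    out = pd.DataFrame(index=over.index.rename("gene"))
    for rep in replicates:
        out[f"n_ge_threshold_{rep}"] = over[rep].astype(int)
        out[f"significant_{rep}"] = over[rep] >= min_shrnas
    out["is_hit"] = np.logical_and.reduce(
        [out[f"significant_{rep}"] for rep in replicates]
    )
    return out.sort_index().reset_index()
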