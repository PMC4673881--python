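"""Genotype-matrix construction from short reads.

The homozygous-inbred panel lets SNP calling be deliberately simple: after
quality trimming and strict alignment filtering, a site is called
homozygous-ALT (coded 2) or homozygous-COM (coded 0) from its read pileup, or
left missing. Two genotype sources (RNAseq-derived calls and an external
genomic panel) are combined, repeated runs of the same accession are merged
by consensus, and the matrix is subjected to minor-allele-frequency and
missingness filters before association testing.

Default thresholds: base quality < 15 trimmed (10-bp windows), alignments
kept with ≤2 mismatches per 36 bp and <5 unaligned tail bases per 75 bp,
calls require base quality ≥ 20 and ≥5 unique supporting reads after
ignoring the 3 terminal aligned bases of each read, and sites with MAF < 1%
or missingness > 60% are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReadRecord",
    "AlignmentRecord",
    "PileupSite",
    "GenotypeMatrix",
    "trim_read",
    "filter_alignment",
    "call_site",
    "merge_consensus",
    "filter_matrix",
    "pileups_from_alignments",
    "read_fastq",
    "write_fastq",
    "read_sam",
    "write_sam",
    "write_vcf",
    "read_vcf",
]

MISSING = -1  # sentinel in the int8 call matrix


@dataclass
class ReadRecord:
    """One sequencing read with integer PHRED qualities (0–40 scale)."""

    id: str
    bases: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities must have equal length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignmentRecord:
    """Simplified ungapped alignment of a read against the reference."""

    read_id: str
    chrom: str
    pos: int  # 0-based reference start
    length: int
    mismatches: int
    tail: int  # unaligned (soft-clipped) bases
    unique: bool
    bases: str = ""
    qualities: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tail < 0 or self.mismatches < 0:
            raise ValueError("tail and mismatch counts must be nonnegative")


@dataclass
class PileupSite:
    """All read observations overlapping one reference position.

    observations: (read id, base, base quality, offset from read start,
    offset from read end), offsets in aligned bases.
    """

    chrom: str
    pos: int  # 0-based
    ref: str
    observations: list[tuple[str, str, int, int, int]]


@dataclass
class GenotypeMatrix:
    """Individuals × biallelic sites with calls in {0, 2, missing}.

    0 = homozygous common allele (COM/COM), 2 = homozygous alternate
    (ALT/ALT), −1 = missing. The COM allele is by construction the majority
    allele at every site.
    """

    individuals: list[str]
    sites: pd.DataFrame  # columns: chrom, pos, com, alt
    calls: np.ndarray  # (n_individuals, n_sites) int8
    source: str = "merged"

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.sites)):
            raise ValueError("calls shape does not match individuals × sites")
        bad = ~np.isin(self.calls, (0, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be 0, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def maf(self) -> np.ndarray:
        """Per-site minor allele frequency over non-missing calls (∈ [0, 0.5])."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        alt = (self.calls == 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(n_obs > 0, alt / np.maximum(n_obs, 1), np.nan)
        return np.minimum(p_alt, 1 - p_alt)

    def missingness(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def site_keys(self) -> pd.Index:
        return pd.Index(zip(self.sites["chrom"], self.sites["pos"]), tupleize_cols=False)

    def take_sites(self, idx: np.ndarray, source: str | None = None) -> "GenotypeMatrix":
        return GenotypeMatrix(
            individuals=list(self.individuals),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
            source=source or self.source,
        )


# ---------------------------------------------------------------------------
# read trimming


def _window_trim_pos(quals: list[int], q_threshold: int, window: int) -> int:
    """Return the truncation length under the sliding-window rule.

    Overlapping windows of `window` bases slide 5'→3' in steps of one base;
    the read is truncated at the start of the first window whose mean quality
    falls below the threshold. Reads shorter than one window are kept whole.
    """
    n = len(quals)
    if n < window:
        return n
    s = sum(quals[:window])
    if s < q_threshold * window:
        return 0
    for start in range(1, n - window + 1):
        s += quals[start + window - 1] - quals[start - 1]
        if s < q_threshold * window:
            return start
    return n


def trim_read(read: ReadRecord, q_threshold: int = 15, window: int = 10) -> ReadRecord:
    """Two-phase quality trimming of one read.

    Phase 1 strips bases from both ends while their quality is below the
    threshold. Phase 2 slides overlapping windows over the remainder and
    truncates at the start of the first window whose mean quality is below
    the threshold. The two phases are iterated to a fixed point, which makes
    the operation idempotent; an empty read is a valid output.
    """
    bases, quals = read.bases, list(read.qualities)
    while True:
        lo, hi = 0, len(quals)
        while lo < hi and quals[lo] < q_threshold:
            lo += 1
        while hi > lo and quals[hi - 1] < q_threshold:
            hi -= 1
        bases, quals = bases[lo:hi], quals[lo:hi]
        cut = _window_trim_pos(quals, q_threshold, window)
        if cut == len(quals) and lo == 0 and hi == len(read.qualities):
            break
        bases, quals = bases[:cut], quals[:cut]
        if not quals:
            break
        read = ReadRecord(id=read.id, bases=bases, qualities=quals)
    return ReadRecord(id=read.id, bases=bases, qualities=quals)


# ---------------------------------------------------------------------------
# alignment filtering


def filter_alignment(aln: AlignmentRecord, mismatch_per: int = 36, tail_per: int = 75) -> bool:
    """Keep an alignment iff it is unique and confidently mapped.

    Allowed: at most 2 mismatches per (started) 36 bp of read length, and
    fewer than 5 unaligned tail bases per (started) 75 bp. Proration uses a
    ceiling on the length ratio; the boundary semantics are ≤2 and <5 per
    unit, matching "two or less" and "fewer than five".
    """
    if not aln.unique:
        return False
    units_mm = math.ceil(aln.length / mismatch_per)
    units_tail = math.ceil(aln.length / tail_per)
    return aln.mismatches <= 2 * units_mm and aln.tail < 5 * units_tail


# ---------------------------------------------------------------------------
# pileup SNP calling


def call_site(
    pileup: PileupSite,
    min_q: int = 20,
    min_reads: int = 5,
    edge: int = 3,
    purity: float = 0.9,
) -> int:
    """Call one site as 0 (COM-hom), 2 (ALT-hom) or missing.

    Observations within `edge` aligned bases of either read end or with base
    quality below `min_q` are discarded. Among the usable observations a
    homozygous call requires at least `min_reads` unique supporting reads and
    a supporting fraction of at least `purity` (the purity rule encodes
    "putative homozygous" for an inbred panel and is exposed as a parameter).
    Anything else is missing.
    """
    usable: dict[str, str] = {}
    for read_id, base, q, off_start, off_end in pileup.observations:
        if off_start < edge or off_end < edge or q < min_q:
            continue
        usable.setdefault(read_id, base)  # unique reads: one observation per id
    if not usable:
        return MISSING
    n = len(usable)
    alt_support = sum(1 for b in usable.values() if b != pileup.ref)
    com_support = n - alt_support
    if alt_support >= min_reads and alt_support / n >= purity:
        return 2
    if com_support >= min_reads and com_support / n >= purity:
        return 0
    return MISSING


def pileups_from_alignments(
    alignments: list[AlignmentRecord], reference: dict[str, str]
) -> dict[tuple[str, int], PileupSite]:
    """Build per-site pileups from simplified (ungapped, full-length) alignments."""
    piles: dict[tuple[str, int], PileupSite] = {}
    for aln in alignments:
        ref_seq = reference[aln.chrom]
        for i in range(aln.length):
            pos = aln.pos + i
            key = (aln.chrom, pos)
            if key not in piles:
                piles[key] = PileupSite(chrom=aln.chrom, pos=pos, ref=ref_seq[pos], observations=[])
            q = aln.qualities[i] if aln.qualities else 40
            piles[key].observations.append((aln.read_id, aln.bases[i], q, i, aln.length - 1 - i))
    return piles


# ---------------------------------------------------------------------------
# consensus merge and matrix filtering


def merge_consensus(runs: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge repeated genotyping runs of the same individuals site-by-site.

    Identical non-missing calls are kept; conflicting non-missing calls are
    scored missing; missing calls are ignored when any concrete call exists.
    The result is order-invariant in `runs`.
    """
    if not runs:
        raise ValueError("no runs to merge")
    first = runs[0]
    keys = first.site_keys()
    for other in runs[1:]:
        if other.individuals != first.individuals:
            raise ValueError("runs must cover identical individuals in order")
        if not keys.equals(other.site_keys()):
            raise ValueError("runs must cover matched site keys")
        same = (other.sites["com"].to_numpy() == first.sites["com"].to_numpy()) & (
            other.sites["alt"].to_numpy() == first.sites["alt"].to_numpy()
        )
        if not same.all():
            raise ValueError("site key collision with different alleles")
    stack = np.stack([m.calls for m in runs])  # (runs, ind, sites)
    any_zero = (stack == 0).any(axis=0)
    any_two = (stack == 2).any(axis=0)
    merged = np.full(first.calls.shape, MISSING, dtype=np.int8)
    merged[any_zero & ~any_two] = 0
    merged[any_two & ~any_zero] = 2
    return GenotypeMatrix(
        individuals=list(first.individuals),
        sites=first.sites.copy(),
        calls=merged,
        source="merged",
    )


def filter_matrix(
    m: GenotypeMatrix,
    maf_min: float = 0.01,
    miss_max: float = 0.60,
    log: dict | None = None,
) -> GenotypeMatrix:
    """Drop sites with MAF below `maf_min` or missingness above `miss_max`.

    MAF is computed on non-missing calls; the missingness bound is strict
    (missing in *over* 60% excluded, exactly 60% kept). Retention counts are
    recorded in `log` when given. An empty result is allowed (warning-level
    event, not an error).
    """
    maf = m.maf()
    miss = m.missingness()
    keep = (np.nan_to_num(maf, nan=0.0) >= maf_min) & (miss <= miss_max)
    if log is not None:
        log.update(
            {
                "n_input": int(m.n_sites),
                "n_kept": int(keep.sum()),
                "n_dropped_maf": int((~(np.nan_to_num(maf, nan=0.0) >= maf_min)).sum()),
                "n_dropped_missing": int((miss > miss_max).sum()),
            }
        )
    return m.take_sites(np.flatnonzero(keep))


def concat_sources(matrices: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Combine genotype sources covering disjoint site sets (same individuals)."""
    first = matrices[0]
    for m in matrices[1:]:
        if m.individuals != first.individuals:
            raise ValueError("sources must cover identical individuals in order")
    sites = pd.concat([m.sites for m in matrices], ignore_index=True)
    calls = np.concatenate([m.calls for m in matrices], axis=1)
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    return GenotypeMatrix(
        individuals=list(first.individuals),
        sites=sites.iloc[order].reset_index(drop=True),
        calls=calls[:, order],
        source="merged",
    )


# ---------------------------------------------------------------------------
# I/O: FASTQ (PHRED+33), minimal SAM, VCF v4.2


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            bases = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            reads.append(
                ReadRecord(id=header.strip()[1:], bases=bases, qualities=[ord(c) - 33 for c in qual])
            )
    return reads


def write_sam(alignments: list[AlignmentRecord], reference: dict[str, str], path: str | Path) -> None:
    """Minimal SAM: ungapped full-length alignments, NM tag for mismatches."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, seq in reference.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        for a in alignments:
            qual = "".join(chr(q + 33) for q in a.qualities) if a.qualities else "*"
            mapq = 60 if a.unique else 0
            fh.write(
                f"{a.read_id}\t0\t{a.chrom}\t{a.pos + 1}\t{mapq}\t{a.length}M\t*\t0\t0\t"
                f"{a.bases}\t{qual}\tNM:i:{a.mismatches}\n"
            )


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            nm = 0
            for tag in f[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
            quals = [] if f[10] == "*" else [ord(c) - 33 for c in f[10]]
            out.append(
                AlignmentRecord(
                    read_id=f[0],
                    chrom=f[2],
                    pos=int(f[3]) - 1,
                    length=len(f[9]),
                    mismatches=nm,
                    tail=0,
                    unique=int(f[4]) > 0,
                    bases=f[9],
                    qualities=quals,
                )
            )
    return out


def write_vcf(m: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as VCF v4.2 with GT calls (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=samgwas:{m.source}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(m.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(m.individuals) + "\n")
        gt_map = {0: "0/0", 2: "1/1", MISSING: "./."}
        for j, site in enumerate(m.sites.itertuples(index=False)):
            gts = "\t".join(gt_map[int(c)] for c in m.calls[:, j])
            fh.write(f"{site.chrom}\t{site.pos + 1}\t.\t{site.com}\t{site.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path, source: str = "merged") -> GenotypeMatrix:
    """Read a VCF of homozygous GT calls back into a GenotypeMatrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, calls = [], []
    for var in vcf:
        rows.append({"chrom": var.CHROM, "pos": var.POS - 1, "com": var.REF, "alt": var.ALT[0]})
        # gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = var.gt_types
        col = np.full(len(individuals), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 3] = 2
        calls.append(col)
    vcf.close()
    return GenotypeMatrix(
        individuals=individuals,
        sites=pd.DataFrame(rows),
        calls=np.array(calls, dtype=np.int8).T if calls else np.zeros((len(individuals), 0), np.int8),
        source=source,
    )


def site_stats_table(m: GenotypeMatrix) -> pd.DataFrame:
    """Per-site MAF/missingness table as written alongside the VCF."""
    return pd.DataFrame(
        {
            "chrom": m.sites["chrom"],
            "pos": m.sites["pos"],
            "com": m.sites["com"],
            "alt": m.sites["alt"],
            "maf": m.maf(),
            "missingness": m.missingness(),
            "source": m.source,
        }
    )
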