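"""Blockwise tabulation of the folded joint site frequency spectrum.

Takes a two-sample VCF plus a BED of intergenic regions, partitions the
regions into fixed-length blocks (default 200 bp), classifies every
biallelic site into one of the four folded mutation types and tallies the
per-block configurations (the bSFS).  Blocks violating the four-gamete
criterion — containing both a fixed difference and a shared heterozygous
site — can be filtered, and blocks may be thinned to every *n*-th for
linkage-aware fitting.

Coordinate conventions: BED intervals are 0-based half-open, VCF positions
1-based; the conversion happens once, at the VCF boundary.  Sites absent
from the VCF count as invariant (variant-only callers).  Sites with any
missing allele or more than two distinct alleles among the four sampled
are excluded from the type counts but tracked per block; blocks whose
excluded-site count exceeds a configurable ceiling are dropped.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "BlockSpectrum",
    "BsfsTally",
    "TabulationResult",
    "read_bed",
    "partition_blocks",
    "classify_site",
    "tabulate_blocks",
    "four_gamete_filter",
    "thin_blocks",
    "tally",
    "filtered_fraction",
]

#: classification outcomes of a single site
SITE_TYPES = ("het_b", "het_v", "shared_het", "fixed_diff", "invariant", "excluded")


class TabulationError(ValueError):
    pass


@dataclass
class BlockSpectrum:
    """Folded mutation-type counts of one block (the bSFS entry)."""

    het_b: int = 0
    het_v: int = 0
    shared_het: int = 0
    fixed_diff: int = 0
    block_id: tuple | None = None  # (contig, start, end), 0-based half-open
    n_excluded_sites: int = 0

    @property
    def config(self) -> tuple[int, int, int, int]:
        return (self.het_b, self.het_v, self.shared_het, self.fixed_diff)

    def __post_init__(self) -> None:
        if min(self.config) < 0 or self.n_excluded_sites < 0:
            raise TabulationError(f"negative count in {self!r}")


@dataclass
class BsfsTally:
    """Multiset of block configurations."""

    counts: dict = field(default_factory=dict)
    n_total_blocks: int = 0
    n_filtered_blocks: int = 0

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def n_recurrent(self) -> int:
        return sum(1 for c in self.counts.values() if c > 1)

    @property
    def n_blocks(self) -> int:
        return sum(self.counts.values())

    def summary(self) -> dict:
        return {
            "n_total_blocks": self.n_total_blocks,
            "n_filtered_blocks": self.n_filtered_blocks,
            "filtered_percent": filtered_fraction(
                self.n_total_blocks, self.n_filtered_blocks
            )
            if self.n_total_blocks
            else 0.0,
            "n_distinct": self.n_distinct,
            "n_recurrent": self.n_recurrent,
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("het_b\thet_v\tshared_het\tfixed_diff\tn_blocks\n")
            for config in sorted(self.counts):
                fh.write("\t".join(map(str, config)) + f"\t{self.counts[config]}\n")

    @classmethod
    def from_tsv(cls, path) -> "BsfsTally":
        counts: dict = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("het_b"):
                raise TabulationError(f"unrecognised tally header in {path}")
            for line in fh:
                *cfg, n = line.split()
                counts[tuple(map(int, cfg))] = int(n)
        t = cls(counts=counts)
        t.n_total_blocks = t.n_blocks
        return t


# ----------------------------------------------------------------------
# blocks
# ----------------------------------------------------------------------


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a BED file into (contig, start, end) tuples, merging any
    overlapping or bookended intervals within a contig."""
    raw: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TabulationError(f"{path}:{ln}: malformed BED line")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise TabulationError(f"{path}:{ln}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise TabulationError(f"{path}:{ln}: invalid interval {start}-{end}")
            raw.append((parts[0], start, end))
    return merge_intervals(raw)


def merge_intervals(intervals) -> list[tuple[str, int, int]]:
    """Merge overlapping intervals per contig; contigs keep first-seen order."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in intervals:
        by_contig.setdefault(contig, []).append((start, end))
    out = []
    for contig, ivs in by_contig.items():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((contig, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((contig, cur_s, cur_e))
    return out


def partition_blocks(regions, block_len: int = 200) -> list[tuple[str, int, int]]:
    """Chop regions into consecutive non-overlapping ``block_len`` windows.

    Windows start at the left end of each interval; a trailing remainder
    shorter than ``block_len`` is dropped.  Output order is contig order
    (first appearance) then coordinate.
    """
    if block_len < 1:
        raise TabulationError("block_len must be >= 1")
    blocks = []
    for contig, start, end in merge_intervals(regions):
        for s in range(start, end - block_len + 1, block_len):
            blocks.append((contig, s, s + block_len))
    return blocks


# ----------------------------------------------------------------------
# site classification
# ----------------------------------------------------------------------


def classify_site(genotype_v, genotype_b) -> str:
    """Classify one site from the two diploid genotypes.

    Genotypes are length-2 sequences of allele identifiers (``None`` or a
    negative integer denotes a missing allele).  Classification is folded:
    only the four sampled alleles matter, never the reference.  Returns one
    of ``het_v``, ``het_b``, ``shared_het``, ``fixed_diff``, ``invariant``
    or ``excluded``.
    """
    if len(genotype_v) != 2 or len(genotype_b) != 2:
        raise TabulationError("genotypes must be diploid")
    alleles = tuple(genotype_v) + tuple(genotype_b)
    if any(a is None or (isinstance(a, int) and a < 0) for a in alleles):
        return "excluded"
    if len(set(alleles)) > 2:
        return "excluded"
    het_v = genotype_v[0] != genotype_v[1]
    het_b = genotype_b[0] != genotype_b[1]
    if het_v and het_b:
        return "shared_het"
    if het_v:
        return "het_v"
    if het_b:
        return "het_b"
    return "fixed_diff" if genotype_v[0] != genotype_b[0] else "invariant"


# ----------------------------------------------------------------------
# tabulation
# ----------------------------------------------------------------------


@dataclass
class TabulationResult:
    spectra: list
    dropped: list  # blocks over the excluded-site ceiling

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def tabulate_blocks(
    blocks,
    vcf_path,
    sample_v: str = "sample_V",
    sample_b: str = "sample_B",
    *,
    excluded_ceiling: float = 0.1,
) -> TabulationResult:
    """Count the four mutation types per block from a two-sample VCF.

    ``blocks`` are 0-based half-open intervals from :func:`partition_blocks`.
    Sites outside every block are ignored; invariant positions need not be
    present in the VCF.  Blocks whose excluded-site count exceeds
    ``excluded_ceiling * block_len`` are dropped and returned separately.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    try:
        iv = samples.index(sample_v)
        ib = samples.index(sample_b)
    except ValueError as exc:
        raise TabulationError(
            f"samples {sample_v!r}/{sample_b!r} not in VCF (has {samples})"
        ) from exc

    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    block_index: dict[str, list[int]] = {}
    spectra = [BlockSpectrum(block_id=b) for b in blocks]
    for i, (contig, s, e) in enumerate(blocks):
        starts.setdefault(contig, []).append(s)
        ends.setdefault(contig, []).append(e)
        block_index.setdefault(contig, []).append(i)

    last: dict[str, int] = {}
    for var in vcf:
        contig, pos0 = var.CHROM, var.POS - 1
        if last.get(contig, -1) > pos0:
            raise TabulationError(f"VCF not sorted at {contig}:{var.POS}")
        last[contig] = pos0
        if contig not in starts:
            continue
        k = bisect_right(starts[contig], pos0) - 1
        if k < 0 or pos0 >= ends[contig][k]:
            continue
        spec = spectra[block_index[contig][k]]
        g = var.genotypes
        cls = classify_site(tuple(g[iv][:2]), tuple(g[ib][:2]))
        if cls == "excluded":
            spec.n_excluded_sites += 1
        elif cls != "invariant":
            setattr(spec, cls, getattr(spec, cls) + 1)

    kept, dropped = [], []
    for spec in spectra:
        block_len = spec.block_id[2] - spec.block_id[1]
        if spec.n_excluded_sites > excluded_ceiling * block_len:
            dropped.append(spec)
        else:
            kept.append(spec)
    return TabulationResult(spectra=kept, dropped=dropped)


def four_gamete_filter(spectra) -> tuple[list, list]:
    """Split blocks into (kept, removed) by the four-gamete criterion.

    A block is removed iff it contains both a fixed difference and a
    shared heterozygous site, which cannot co-occur in a non-recombining
    block under infinite sites.
    """
    kept, removed = [], []
    for s in spectra:
        (removed if s.fixed_diff > 0 and s.shared_het > 0 else kept).append(s)
    return kept, removed


def thin_blocks(spectra, step: int = 1000) -> list:
    """Every ``step``-th block in genomic order (indices 0, step, 2·step…)."""
    if step < 1:
        raise TabulationError("step must be >= 1")
    return list(spectra[::step])


def tally(spectra, n_filtered: int = 0) -> BsfsTally:
    """Exact multiset count of block configurations."""
    counts = Counter(s.config for s in spectra)
    return BsfsTally(
        counts=dict(counts),
        n_total_blocks=len(spectra) + n_filtered,
        n_filtered_blocks=n_filtered,
    )


def filtered_fraction(n_total: int, n_removed: int) -> float:
    """Percentage of blocks removed, rounded to two decimals."""
    if n_total <= 0:
        raise TabulationError("n_total must be positive")
    return round(n_removed / n_total * 100.0, 2)
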