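"""Structured-coalescent simulator for one diploid genome per species.

Simulates genealogies of the four sampled alleles (two per species) under a
:class:`~blockcoal.models.DemographyModel`, resolving total branch length
into the four folded mutation classes of a 200-bp block spectrum:

* ``het_b``   — branches subtending one B allele (or its folded complement),
* ``het_v``   — branches subtending one V allele,
* ``shared_het`` — branches subtending one allele of each species,
* ``fixed_diff`` — branches subtending both alleles of one species.

Mutations are dropped on the genealogy under an infinite-sites model: the
count in class *i* is Poisson with mean ``theta_block * tau_i``, where
``tau_i`` is the class length in units of ``2 * Ne_ref`` generations and
``theta_block`` is the expected number of mutations per block per unit
branch length (``theta_block = 2 * Ne_ref * mu * block_len``).

Blocks are simulated independently (free recombination between blocks) and
all sites within a block share one genealogy (no recombination within a
block).  The module doubles as the Monte-Carlo oracle behind the analytic
likelihood and as a fixture factory writing VCF/BED/FASTA triplets that
round-trip exactly through the tabulator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import FLOW_ADM, FLOW_IM, DemographyModel, ModelError

__all__ = [
    "BranchClassLengths",
    "SimConfig",
    "simulate_genealogy",
    "simulate_branch_lengths",
    "simulate_spectrum_counts",
    "simulate_block_spectra",
    "simulate_genotype_fixture",
]

CLASS_NAMES = ("het_b", "het_v", "shared_het", "fixed_diff")

# class index of a lineage subtending nv alleles of V and nb of B (folded)
_CLASS_OF = {
    (0, 1): 0,
    (2, 1): 0,
    (1, 0): 1,
    (1, 2): 1,
    (1, 1): 2,
    (2, 0): 3,
    (0, 2): 3,
}


@dataclass(frozen=True)
class BranchClassLengths:
    """Class-resolved branch lengths of one genealogy (units: 2·Ne_ref gens)."""

    tau_hetB: float
    tau_hetV: float
    tau_shared: float
    tau_fixed: float

    @property
    def total(self) -> float:
        return self.tau_hetB + self.tau_hetV + self.tau_shared + self.tau_fixed

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.tau_hetB, self.tau_hetV, self.tau_shared, self.tau_fixed]
        )


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a block-spectrum simulation.

    ``theta_block`` is the expected number of mutations per block on a
    branch of length one (time unit ``2 * Ne_ref`` generations), i.e.
    ``2 * Ne_ref * mu * block_len``.
    """

    model: DemographyModel
    theta_block: float
    n_blocks: int
    block_len: int = 200
    seed: int = 0
    missing_fraction: float = 0.0

    def validate(self) -> None:
        self.model.validate()
        if not self.theta_block > 0:
            raise ValueError("theta_block must be > 0")
        if self.block_len < 1:
            raise ValueError("block_len must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")


# ----------------------------------------------------------------------
# genealogy simulation
# ----------------------------------------------------------------------


def _one_genealogy(model: DemographyModel, rng: np.random.Generator) -> np.ndarray:
    """Gillespie simulation of one genealogy; returns the four class lengths.

    Lineages are ``[deme, nv, nb]`` triples.  Events are pairwise
    coalescence within a deme (rate ``1/c_deme`` per pair), backwards
    migration of single lineages (IM models), an instantaneous admixture
    pulse at ``t_adm`` (ADM models) and the merger of both demes into the
    ancestor at ``t_split``.
    """
    t_split = model.t_split
    sizes = {"V": model.c_v, "B": model.c_b, "A": 1.0}
    # backwards in time, lineages in the forward-recipient deme jump to the donor
    mig_src = model.recipient if model.flow == FLOW_IM else None
    mig_rate = model.m if model.flow == FLOW_IM else 0.0

    if t_split == 0.0:
        lineages = [["A", 1, 0], ["A", 1, 0], ["A", 0, 1], ["A", 0, 1]]
        boundaries: list[tuple[float, str]] = []
    else:
        lineages = [["V", 1, 0], ["V", 1, 0], ["B", 0, 1], ["B", 0, 1]]
        boundaries = [(t_split, "split")]
        if model.flow == FLOW_ADM:
            boundaries.insert(0, (model.t_adm, "pulse"))

    tau = np.zeros(4)
    t = 0.0
    exp = rng.exponential
    while len(lineages) > 1:
        # per-deme lineage counts -> coalescence rates
        rates = []
        total = 0.0
        by_deme: dict[str, int] = {}
        for lin in lineages:
            by_deme[lin[0]] = by_deme.get(lin[0], 0) + 1
        for deme, k in by_deme.items():
            r = k * (k - 1) / 2.0 / sizes[deme]
            if r > 0.0:
                rates.append(("coal", deme, r))
                total += r
        if mig_src is not None and mig_rate > 0.0:
            k = by_deme.get(mig_src, 0)
            if k:
                rates.append(("mig", mig_src, k * mig_rate))
                total += k * mig_rate

        if total > 0.0:
            dt = exp(1.0 / total)
        else:
            dt = math.inf
        t_next = t + dt
        if boundaries and t_next >= boundaries[0][0]:
            b_time, b_kind = boundaries.pop(0)
            _accrue(tau, lineages, b_time - t)
            t = b_time
            if b_kind == "pulse":
                f = model.f
                rec, don = model.recipient, model.donor
                for lin in lineages:
                    if lin[0] == rec and rng.random() < f:
                        lin[0] = don
            else:  # split: both demes merge into the ancestor
                for lin in lineages:
                    lin[0] = "A"
            continue

        _accrue(tau, lineages, dt)
        t = t_next
        u = rng.random() * total
        acc = 0.0
        for kind, deme, r in rates:
            acc += r
            if u <= acc:
                break
        if kind == "coal":
            idx = [i for i, lin in enumerate(lineages) if lin[0] == deme]
            i, j = rng.choice(len(idx), size=2, replace=False)
            a, b = lineages[idx[i]], lineages[idx[j]]
            merged = [deme, a[1] + b[1], a[2] + b[2]]
            for k in sorted((idx[i], idx[j]), reverse=True):
                lineages.pop(k)
            lineages.append(merged)
        else:  # migration
            idx = [i for i, lin in enumerate(lineages) if lin[0] == deme]
            i = idx[int(rng.integers(len(idx)))]
            lineages[i][0] = model.donor
    return tau


def _accrue(tau: np.ndarray, lineages: list, dt: float) -> None:
    for lin in lineages:
        c = _CLASS_OF.get((lin[1], lin[2]))
        if c is not None:
            tau[c] += dt


def simulate_genealogy(model: DemographyModel, seed: int) -> BranchClassLengths:
    """Simulate one genealogy of the (2, 2) sample under ``model``."""
    model.validate()
    rng = np.random.default_rng(seed)
    tau = _one_genealogy(model, rng)
    return BranchClassLengths(*map(float, tau))


def simulate_branch_lengths(
    model: DemographyModel,
    n_sims: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate ``n_sims`` genealogies; returns an ``(n_sims, 4)`` array of
    class lengths ordered (het_b, het_v, shared_het, fixed_diff)."""
    model.validate()
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = np.empty((n_sims, 4))
    for i in range(n_sims):
        out[i] = _one_genealogy(model, rng)
    return out


# ----------------------------------------------------------------------
# block spectra
# ----------------------------------------------------------------------


def simulate_spectrum_counts(cfg: SimConfig) -> np.ndarray:
    """Simulate per-block mutation-class counts.

    Returns an ``(n_blocks, 4)`` integer array in the fixed
    (het_b, het_v, shared_het, fixed_diff) ordering; deterministic given
    ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    taus = simulate_branch_lengths(cfg.model, cfg.n_blocks, rng)
    return rng.poisson(cfg.theta_block * taus).astype(np.int64)


def simulate_block_spectra(cfg: SimConfig):
    """Simulate independent blocks and return them as ``BlockSpectrum`` records.

    One genealogy per block; within-block mutation counts are Poisson with
    mean ``theta_block * tau_class``.
    """
    from .tabulate import BlockSpectrum  # local import: avoid cycle

    counts = simulate_spectrum_counts(cfg)
    L = cfg.block_len
    return [
        BlockSpectrum(
            het_b=int(c[0]),
            het_v=int(c[1]),
            shared_het=int(c[2]),
            fixed_diff=int(c[3]),
            block_id=("sim", i * L, (i + 1) * L),
        )
        for i, c in enumerate(counts)
    ]


# ----------------------------------------------------------------------
# on-disk fixtures
# ----------------------------------------------------------------------

_BASES = "ACGT"

# genotype patterns realizing each mutation class, as (V, B) allele pairs
# (0 = REF, 1 = ALT); folding makes the choice of which side is ALT arbitrary
_CLASS_GT = {
    0: ((0, 0), (0, 1)),  # het_b
    1: ((0, 1), (0, 0)),  # het_v
    2: ((0, 1), (0, 1)),  # shared_het
    3: ((1, 1), (0, 0)),  # fixed_diff
}


@dataclass
class FixtureSummary:
    """What :func:`simulate_genotype_fixture` wrote."""

    n_blocks: int
    n_sites: int
    n_missing_sites: int
    contig: str
    contig_length: int
    paths: dict = field(default_factory=dict)


def simulate_genotype_fixture(
    cfg: SimConfig,
    out_vcf: str | Path,
    out_bed: str | Path,
    out_fasta: str | Path,
    *,
    contig: str = "chr1",
    sample_v: str = "sample_V",
    sample_b: str = "sample_B",
) -> FixtureSummary:
    """Write a reference FASTA, an 'intergenic' BED and a two-sample VCF whose
    per-block site patterns realize the simulated block spectra exactly.

    Blocks are laid out consecutively on a single contig; the BED holds one
    interval per block.  Mutation positions are uniform within the block and
    sampled without replacement (infinite sites).  A JSON sidecar
    (``<out_vcf>.truth.json``) records the generating parameters and seed.
    """
    cfg.validate()
    counts = simulate_spectrum_counts(cfg)
    rng = np.random.default_rng((cfg.seed, 0xF1C))  # placement stream
    L = cfg.block_len
    n_blocks = cfg.n_blocks
    contig_length = n_blocks * L

    seq = rng.integers(0, 4, size=contig_length)

    vcf_lines: list[str] = []
    n_sites = 0
    n_missing = 0
    for b in range(n_blocks):
        tot = int(counts[b].sum())
        if tot > L:
            raise ValueError(
                f"block {b}: {tot} mutations cannot be placed in {L} bases "
                "under infinite sites"
            )
        if tot == 0:
            continue
        pos = np.sort(rng.choice(L, size=tot, replace=False)) + b * L
        classes = np.repeat(np.arange(4), counts[b])
        rng.shuffle(classes)
        for p, cls in zip(pos, classes):
            ref = _BASES[seq[p]]
            alt = _BASES[(seq[p] + 1 + int(rng.integers(3))) % 4]
            gt_v, gt_b = _CLASS_GT[int(cls)]
            if cfg.missing_fraction > 0.0 and rng.random() < cfg.missing_fraction:
                gt_v_s = "./."
                n_missing += 1
            else:
                gt_v_s = f"{gt_v[0]}/{gt_v[1]}"
            gt_b_s = f"{gt_b[0]}/{gt_b[1]}"
            vcf_lines.append(
                f"{contig}\t{p + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt_v_s}\t{gt_b_s}"
            )
            n_sites += 1

    out_vcf, out_bed, out_fasta = Path(out_vcf), Path(out_bed), Path(out_fasta)
    with open(out_fasta, "w") as fh:
        fh.write(f">{contig}\n")
        s = "".join(_BASES[i] for i in seq)
        for i in range(0, len(s), 60):
            fh.write(s[i : i + 60] + "\n")

    with open(out_bed, "w") as fh:
        for b in range(n_blocks):
            fh.write(f"{contig}\t{b * L}\t{(b + 1) * L}\n")

    with open(out_vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_v}\t{sample_b}\n"
        )
        fh.write("\n".join(vcf_lines))
        if vcf_lines:
            fh.write("\n")

    truth = {
        "model_id": cfg.model.model_id,
        "flow": cfg.model.flow,
        "donor": cfg.model.donor,
        "deviating": cfg.model.deviating,
        "t_split": cfg.model.t_split,
        "c_x": cfg.model.c_x,
        "m": cfg.model.m,
        "f": cfg.model.f,
        "t_adm": cfg.model.t_adm,
        "theta_block": cfg.theta_block,
        "n_blocks": cfg.n_blocks,
        "block_len": cfg.block_len,
        "seed": cfg.seed,
        "missing_fraction": cfg.missing_fraction,
        "samples": {"V": sample_v, "B": sample_b},
    }
    truth_path = Path(str(out_vcf) + ".truth.json")
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")

    return FixtureSummary(
        n_blocks=n_blocks,
        n_sites=n_sites,
        n_missing_sites=n_missing,
        contig=contig,
        contig_length=contig_length,
        paths={
            "vcf": str(out_vcf),
            "bed": str(out_bed),
            "fasta": str(out_fasta),
            "truth": str(truth_path),
        },
    )
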