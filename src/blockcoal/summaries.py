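"""Diversity summaries and conversion of fits into demographic units.

Dimensionless composite-likelihood estimates are converted to effective
population sizes, split times in generations/years and per-generation
migration rates under a mutation-rate/generation-time calibration.  The
scaled-mutation-rate convention used throughout the package is

    theta_block = 2 * Ne_ref * mu * block_len

i.e. ``theta_block`` is the expected number of mutations per block on a
branch of length one with time measured in ``2 * Ne_ref`` generations.
Equivalently the per-site nucleotide diversity implied by a fit is
``2 * theta_block / block_len = 4 * Ne_ref * mu`` within a deme of
relative size 1.

Also provides genome-wide pi/dxy/FST from a two-sample VCF and the
mean-mother-age generation-length estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Calibration",
    "ScaledEstimates",
    "scale_estimates",
    "mutation_rate_from_divergence",
    "diversity_stats",
    "generation_length",
]


@dataclass(frozen=True)
class Calibration:
    """Mutation-rate and generation-time calibration."""

    mu: float  # mutations per site per generation
    g: float  # years per generation
    block_len: int = 200

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if not self.g > 0:
            raise ValueError("g must be > 0")
        if self.block_len < 1:
            raise ValueError("block_len must be >= 1")


@dataclass(frozen=True)
class ScaledEstimates:
    """Demographic-unit estimates under one calibration.

    Migration is reported under two labelled conventions because the
    number of migrants per generation is scaler-dependent:
    ``migrants_Nm = Ne_recipient * m_per_generation`` and
    ``migrants_4Nm = 4 * Ne_recipient * m_per_generation``.
    """

    Ne_ref: float
    Ne_V: float
    Ne_B: float
    Ne_anc: float
    T_split_generations: float
    T_split_years: float
    m_per_generation: float | None = None
    migrants_Nm: float | None = None
    migrants_4Nm: float | None = None
    f: float | None = None
    T_adm_generations: float | None = None
    T_adm_years: float | None = None
    calibration: Calibration | None = None

    def as_dict(self) -> dict:
        d = {
            "Ne_ref": self.Ne_ref,
            "Ne_V": self.Ne_V,
            "Ne_B": self.Ne_B,
            "Ne_anc": self.Ne_anc,
            "T_split_generations": self.T_split_generations,
            "T_split_years": self.T_split_years,
            "m_per_generation": self.m_per_generation,
            "migrants_Nm": self.migrants_Nm,
            "migrants_4Nm": self.migrants_4Nm,
            "f": self.f,
            "T_adm_generations": self.T_adm_generations,
            "T_adm_years": self.T_adm_years,
        }
        if self.calibration is not None:
            d["mu"] = self.calibration.mu
            d["generation_years"] = self.calibration.g
            d["block_len"] = self.calibration.block_len
        return d


def scale_estimates(fit, cal: Calibration) -> ScaledEstimates:
    """Convert a :class:`~blockcoal.inference.FitResult` to natural units.

    ``Ne_ref = theta_block / (2 * mu * block_len)`` (the ancestor is the
    reference size class); deme sizes scale by their relative sizes;
    ``T_split_generations = t_split * 2 * Ne_ref``;
    ``m_per_generation = m / (2 * Ne_ref)``.
    """
    if not getattr(fit, "converged", True):
        raise ValueError("cannot scale a non-converged fit")
    mle = fit.mle
    model = fit.model
    theta = mle["theta"]
    ne_ref = theta / (2.0 * cal.mu * cal.block_len)
    t_gen = mle["t_split"] * 2.0 * ne_ref
    kwargs: dict = {}
    if "m" in mle:
        m_per_gen = mle["m"] / (2.0 * ne_ref)
        ne_recipient = ne_ref * model.size_of(model.recipient)
        kwargs.update(
            m_per_generation=m_per_gen,
            migrants_Nm=ne_recipient * m_per_gen,
            migrants_4Nm=4.0 * ne_recipient * m_per_gen,
        )
    if "f" in mle:
        t_adm_gen = mle["t_adm"] * 2.0 * ne_ref
        kwargs.update(
            f=mle["f"],
            T_adm_generations=t_adm_gen,
            T_adm_years=t_adm_gen * cal.g,
        )
    return ScaledEstimates(
        Ne_ref=ne_ref,
        Ne_V=ne_ref * model.c_v,
        Ne_B=ne_ref * model.c_b,
        Ne_anc=ne_ref * model.c_anc,
        T_split_generations=t_gen,
        T_split_years=t_gen * cal.g,
        calibration=cal,
        **kwargs,
    )


def mutation_rate_from_divergence(
    pairwise_distance: float, t_total_generations: float
) -> float:
    """Per-generation mutation rate implied by a pairwise distance.

    ``t_total_generations`` is the *total* separation along both branches,
    i.e. twice the split time in generations; the returned rate is
    ``pairwise_distance / t_total_generations``.
    """
    if pairwise_distance < 0:
        raise ValueError("pairwise_distance must be >= 0")
    if not t_total_generations > 0:
        raise ValueError("t_total_generations must be > 0")
    return pairwise_distance / t_total_generations


def diversity_stats(
    vcf_path,
    callable_sites: int,
    sample_v: str = "sample_V",
    sample_b: str = "sample_B",
    *,
    fst_estimator: str = "hudson",
) -> dict:
    """Genome-wide per-site pi (per sample), dxy and FST from a VCF.

    ``pi`` is the heterozygous-site density of each diploid sample;
    ``dxy`` averages, per site, the fraction of the four between-species
    allele pairs that differ (invariant sites contribute zero, so only the
    VCF records matter); ``callable_sites`` is the denominator for all
    three.  FST defaults to the Hudson form ``1 - mean(pi) / dxy``; the
    ``"ratio"`` estimator ``(dxy - mean(pi)) / (dxy + mean(pi))`` is also
    available.  The estimator used is labelled in the output; FST is None
    when dxy is zero.
    """
    from cyvcf2 import VCF

    from .tabulate import TabulationError, classify_site

    if callable_sites <= 0:
        raise ValueError("callable_sites must be > 0")
    if fst_estimator not in ("hudson", "ratio"):
        raise ValueError(f"unknown fst estimator {fst_estimator!r}")

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    try:
        iv, ib = samples.index(sample_v), samples.index(sample_b)
    except ValueError as exc:
        raise TabulationError(f"samples not found in VCF (has {samples})") from exc

    n_het_v = n_het_b = 0
    dxy_sum = 0.0
    for var in vcf:
        g = var.genotypes
        gv, gb = tuple(g[iv][:2]), tuple(g[ib][:2])
        cls = classify_site(gv, gb)
        if cls == "excluded":
            continue
        if cls in ("het_v", "shared_het"):
            n_het_v += 1
        if cls in ("het_b", "shared_het"):
            n_het_b += 1
        # fraction of the 2x2 between-species allele pairs that differ
        diff = sum(1 for a in gv for b in gb if a != b)
        dxy_sum += diff / 4.0

    pi_v = n_het_v / callable_sites
    pi_b = n_het_b / callable_sites
    dxy = dxy_sum / callable_sites
    pi_w = 0.5 * (pi_v + pi_b)
    if dxy == 0.0:
        fst = None
    elif fst_estimator == "hudson":
        fst = 1.0 - pi_w / dxy
    else:
        fst = (dxy - pi_w) / (dxy + pi_w)
    return {
        "pi_V": pi_v,
        "pi_B": pi_b,
        "dxy": dxy,
        "fst": fst,
        "fst_estimator": fst_estimator,
        "callable_sites": callable_sites,
    }


def generation_length(age_classes) -> float:
    """Mean age of the mothers of all offspring.

    ``age_classes`` holds ``(age_years, n_breeding_females, fecundity)``
    triples; returns ``G = sum(a * n * m) / sum(n * m)``.
    """
    num = den = 0.0
    for age, n, fec in age_classes:
        if age < 0 or n < 0 or fec < 0:
            raise ValueError("age classes must be non-negative")
        num += age * n * fec
        den += n * fec
    if den == 0.0:
        raise ValueError("all-zero offspring weights")
    return num / den
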