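"""Two-taxon demographic scenarios.

A :class:`DemographyModel` describes the history of two species, labelled
``V`` and ``B``, that diverged from a common ancestor at time ``t_split``
(measured in units of ``2 * Ne_ref`` generations, with the ancestral
population as the reference size class).  Post-divergence gene flow is
either absent, continuous (isolation with migration), or a single discrete
admixture pulse.  Effective sizes are expressed relative to the ancestor:
the ancestor is fixed at 1 and at most one species (``deviating``) carries
a free relative size ``c_x``; every other deme has relative size 1.

Directions are forward in time: ``donor="B"`` means gene flow from species
B into species V.  Backwards in time (the coalescent view) this moves
lineages currently in V into B.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

SPECIES = ("V", "B")

#: gene-flow modes
FLOW_NONE = "none"
FLOW_IM = "im"
FLOW_ADM = "adm"


class ModelError(ValueError):
    """Raised for structurally invalid demographic models."""


@dataclass(frozen=True)
class DemographyModel:
    """One divergence/migration/admixture scenario.

    Parameters
    ----------
    model_id:
        Stable identifier, e.g. ``"M3.3"``.
    flow:
        ``"none"`` (strict divergence), ``"im"`` (continuous migration) or
        ``"adm"`` (single admixture pulse).
    donor:
        Forward-time source species of gene flow (``"V"`` or ``"B"``), or
        ``None`` when ``flow == "none"``.
    deviating:
        Species whose relative size ``c_x`` is free; ``None`` for the
        single-size-class scenarios.
    t_split, c_x, m, f, t_adm:
        Bound parameter values (dimensionless; time in units of
        ``2 * Ne_ref`` generations, ``m`` per lineage per unit time).
        ``None`` until bound via :meth:`with_params`.
    """

    model_id: str
    flow: str = FLOW_NONE
    donor: str | None = None
    deviating: str | None = None
    t_split: float | None = None
    c_x: float | None = None
    m: float | None = None
    f: float | None = None
    t_adm: float | None = None

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    @property
    def recipient(self) -> str | None:
        """Forward-time sink species of gene flow."""
        if self.donor is None:
            return None
        return "V" if self.donor == "B" else "B"

    @property
    def c_v(self) -> float:
        return float(self.c_x) if self.deviating == "V" else 1.0

    @property
    def c_b(self) -> float:
        return float(self.c_x) if self.deviating == "B" else 1.0

    @property
    def c_anc(self) -> float:
        return 1.0

    @property
    def param_names(self) -> tuple[str, ...]:
        """Free parameters of the scenario (the fit vector), theta first."""
        names = ["theta", "t_split"]
        if self.deviating is not None:
            names.append("c_x")
        if self.flow == FLOW_IM:
            names.append("m")
        elif self.flow == FLOW_ADM:
            names.extend(["f", "t_adm"])
        return tuple(names)

    @property
    def n_free_params(self) -> int:
        return len(self.param_names)

    @property
    def type_label(self) -> str:
        """Human-readable scenario label, e.g. ``"IM 2 B(x)->V"``."""
        n_ne = 1 if self.deviating is None else 2
        if self.flow == FLOW_NONE:
            return f"DIV {n_ne}"
        kind = "IM" if self.flow == FLOW_IM else "ADM"
        dn, rc = self.donor, self.recipient
        mark_d = "(x)" if self.deviating == dn else ""
        mark_r = "(x)" if self.deviating == rc else ""
        return f"{kind} {n_ne} {dn}{mark_d}->{rc}{mark_r}"

    # ------------------------------------------------------------------
    # binding and validation
    # ------------------------------------------------------------------
    def with_params(self, **values: float) -> "DemographyModel":
        """Return a copy with the given parameter values bound.

        Only names in :attr:`param_names` (minus ``theta``, which lives
        outside the model) are accepted.
        """
        allowed = set(self.param_names) - {"theta"}
        bad = set(values) - allowed
        if bad:
            raise ModelError(
                f"{self.model_id}: parameters {sorted(bad)} not free in this model "
                f"(free: {sorted(allowed)})"
            )
        return dataclasses.replace(self, **values)

    def validate(self, *, require_bound: bool = True) -> None:
        """Check structural and numeric invariants; raise :class:`ModelError`."""
        if self.flow not in (FLOW_NONE, FLOW_IM, FLOW_ADM):
            raise ModelError(f"unknown gene-flow mode {self.flow!r}")
        if self.flow == FLOW_NONE and self.donor is not None:
            raise ModelError("donor given but flow is 'none'")
        if self.flow != FLOW_NONE and self.donor not in SPECIES:
            raise ModelError(f"donor must be one of {SPECIES}")
        if self.deviating is not None and self.deviating not in SPECIES:
            raise ModelError(f"deviating species must be one of {SPECIES}")
        if not require_bound:
            return
        if self.t_split is None or self.t_split < 0:
            raise ModelError("t_split must be bound and >= 0")
        if self.deviating is not None and (self.c_x is None or self.c_x <= 0):
            raise ModelError("c_x must be bound and > 0")
        if self.flow == FLOW_IM:
            if self.m is None or self.m < 0 or not _finite(self.m):
                raise ModelError("m must be bound, finite and >= 0")
        if self.flow == FLOW_ADM:
            if self.f is None or not 0.0 <= self.f <= 1.0:
                raise ModelError("f must be bound and in [0, 1]")
            if self.t_adm is None or not 0.0 < self.t_adm:
                raise ModelError("t_adm must be bound and > 0")
            if self.t_adm > self.t_split:
                raise ModelError("t_adm must not exceed t_split")

    def size_of(self, deme: str) -> float:
        """Relative size of a deme (``"V"``, ``"B"`` or ``"A"``)."""
        if deme == "V":
            return self.c_v
        if deme == "B":
            return self.c_b
        if deme == "A":
            return self.c_anc
        raise ModelError(f"unknown deme {deme!r}")


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def panmictic(model_id: str = "PAN") -> DemographyModel:
    """Degenerate single-population control: a DIV model with ``t_split = 0``."""
    return DemographyModel(model_id=model_id, t_split=0.0)
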