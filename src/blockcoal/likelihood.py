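"""Analytic probabilities of blockwise mutational configurations.

For a demographic model and per-block scaled mutation rate ``theta_block``,
the probability of observing the configuration ``(k_hetB, k_hetV,
k_shared, k_fixed)`` in a non-recombining block is

    P(k) = E[ prod_i Poisson(k_i; theta_block * tau_i) ]

with the expectation over genealogies of the four sampled alleles and
``tau_i`` the branch length falling in folded mutation class *i*.

The computation augments the structured-coalescent Markov chain over
lineage configurations with the four (truncated) mutation counters:
mutations of class *i* occur at rate ``theta_block`` per lineage whose
subtended leaf subset maps to class *i*, incrementing counter *i*; counts
beyond ``k_max`` are lumped into a per-class overflow category.  The
pre-split epoch is propagated with a sparse matrix exponential (with the
admixture pulse applied as an instantaneous stochastic relabelling), the
absorbing single-deme ancestral epoch is solved exactly as a linear
system.  The resulting table over ``(k_max + 2)^4`` cells is exact up to
sparse-linear-algebra tolerances and sums to one.

Two interchangeable state-space representations are provided: leaf-labelled
(every lineage keeps its exact leaf subset) and lumped (lineages reduced to
their per-species leaf counts, exact by exchangeability of the two alleles
within a species).  The lumped space is roughly four times smaller and is
the default; tests cross-check the two.  A Rao-Blackwellised Monte-Carlo
oracle (:func:`mc_config_probability`) provides an independent route.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply, splu
from scipy.stats import poisson

from .models import FLOW_ADM, FLOW_IM, DemographyModel

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_NAMES",
    "branch_class_of",
    "build_state_space",
    "config_probability",
    "config_distribution",
    "ConfigProbabilityTable",
    "mc_config_probability",
    "mc_config_table",
    "composite_loglik",
    "PROB_FLOOR",
]

CLASS_NAMES = ("het_b", "het_v", "shared_het", "fixed_diff")
LEAVES = ("v1", "v2", "b1", "b2")

#: floor applied to per-configuration probabilities before taking logs
PROB_FLOOR = 1e-300

#: probabilities more negative than this indicate numerical failure
NEG_TOL = 1e-10

_CLASS_OF_NVNB = {
    (0, 1): 0,
    (2, 1): 0,
    (1, 0): 1,
    (1, 2): 1,
    (1, 1): 2,
    (2, 0): 3,
    (0, 2): 3,
}


def branch_class_of(subset) -> str:
    """Folded mutation class of a branch subtending ``subset`` of the leaves.

    ``subset`` is any iterable over leaf names from ``("v1", "v2", "b1",
    "b2")``.  A subset and its complement map to the same class (folding).
    Raises ``ValueError`` for the empty or full subset, where a mutation
    would be unobservable.
    """
    s = frozenset(subset)
    if not s <= frozenset(LEAVES):
        raise ValueError(f"unknown leaves in subset: {sorted(s)}")
    if len(s) == 0 or len(s) == len(LEAVES):
        raise ValueError("mutations on the empty or full subset are unobservable")
    nv = len(s & {"v1", "v2"})
    nb = len(s & {"b1", "b2"})
    return CLASS_NAMES[_CLASS_OF_NVNB[(nv, nb)]]


# ----------------------------------------------------------------------
# state spaces
# ----------------------------------------------------------------------
#
# A lineage is a (deme, key) pair.  Labelled representation: key is a sorted
# tuple of leaf names.  Lumped representation: key is (nv, nb).  States are
# sorted tuples of lineages; any fully coalesced state is canonicalised to
# a single MRCA state (further events are unobservable).

_MRCA_LAB = (("A", tuple(sorted(LEAVES))),)
_MRCA_LUM = (("A", (2, 2)),)


def _nvnb(key) -> tuple[int, int]:
    if isinstance(key[0], str):
        return (
            sum(1 for x in key if x.startswith("v")),
            sum(1 for x in key if x.startswith("b")),
        )
    return key


def _merge(k1, k2):
    if isinstance(k1[0], str):
        return tuple(sorted(k1 + k2))
    return (k1[0] + k2[0], k1[1] + k2[1])


def _canon(lineages, mrca):
    if len(lineages) == 1:
        return mrca
    return tuple(sorted(lineages))


@dataclass(frozen=True)
class EpochSpace:
    """Enumerated lineage configurations of one epoch with rate structure.

    ``trans`` rows are ``(i, j, tag, coeff)``: a transition from state *i*
    to *j* at rate ``coeff * scale(tag)`` where the scale is ``1/c_deme``
    for coalescence tags and ``m`` for migration.  ``class_counts[i, c]``
    is the number of lineages of state *i* accruing length into mutation
    class *c*.
    """

    states: tuple
    index: dict
    trans: tuple  # of (i, j, tag, coeff)
    class_counts: np.ndarray
    mrca_idx: int


_TAGS = ("coal:V", "coal:B", "coal:A", "mig")


def _enumerate_space(initial_states, mrca, mig_route, reach_routes) -> EpochSpace:
    """BFS over lineage configurations.

    ``mig_route = (src, dst)`` adds rate-carrying migration transitions;
    ``reach_routes`` adds deme moves for reachability only (admixture
    pulses), without rates.
    """
    states: list = []
    index: dict = {}
    trans: list = []

    def add(s):
        if s not in index:
            index[s] = len(states)
            states.append(s)
        return index[s]

    stack = [add(_canon(s, mrca)) for s in initial_states]
    seen_from = set()
    while stack:
        i = stack.pop()
        if i in seen_from:
            continue
        seen_from.add(i)
        s = states[i]
        if s == mrca:
            continue
        lin = list(s)
        # coalescence: every unordered pair in the same deme
        for a, b in combinations(range(len(lin)), 2):
            if lin[a][0] != lin[b][0]:
                continue
            deme = lin[a][0]
            merged = (deme, _merge(lin[a][1], lin[b][1]))
            new = _canon(
                [l for k, l in enumerate(lin) if k not in (a, b)] + [merged], mrca
            )
            j = add(new)
            stack.append(j)
            trans.append((i, j, f"coal:{deme}", 1.0))
        # migration (rate) transitions
        if mig_route is not None:
            src, dst = mig_route
            for a in range(len(lin)):
                if lin[a][0] != src:
                    continue
                moved = list(lin)
                moved[a] = (dst, lin[a][1])
                j = add(_canon(moved, mrca))
                stack.append(j)
                trans.append((i, j, "mig", 1.0))
        # reachability-only moves (admixture pulse targets)
        for src, dst in reach_routes:
            for a in range(len(lin)):
                if lin[a][0] != src:
                    continue
                moved = list(lin)
                moved[a] = (dst, lin[a][1])
                stack.append(add(_canon(moved, mrca)))

    # merge duplicate (i, j, tag) rows into coefficients
    agg: dict = {}
    for i, j, tag, c in trans:
        agg[(i, j, tag)] = agg.get((i, j, tag), 0.0) + c
    trans_t = tuple((i, j, tag, c) for (i, j, tag), c in sorted(agg.items()))

    n = len(states)
    cc = np.zeros((n, 4))
    for i, s in enumerate(states):
        if s == mrca:
            continue
        for deme, key in s:
            c = _CLASS_OF_NVNB.get(_nvnb(key))
            if c is not None:
                cc[i, c] += 1.0
    return EpochSpace(
        states=tuple(states),
        index=dict(index),
        trans=trans_t,
        class_counts=cc,
        mrca_idx=index.get(mrca, -1),
    )


def _initial_state(lumped: bool, deme_v="V", deme_b="B"):
    if lumped:
        return tuple(
            sorted([(deme_v, (1, 0)), (deme_v, (1, 0)), (deme_b, (0, 1)), (deme_b, (0, 1))])
        )
    return tuple(
        sorted(
            [(deme_v, ("v1",)), (deme_v, ("v2",)), (deme_b, ("b1",)), (deme_b, ("b2",))]
        )
    )


@lru_cache(maxsize=None)
def _presplit_space(flow: str, donor: str | None, lumped: bool) -> EpochSpace:
    mrca = _MRCA_LUM if lumped else _MRCA_LAB
    recipient = None if donor is None else ("V" if donor == "B" else "B")
    mig_route = (recipient, donor) if flow == FLOW_IM else None
    reach = ((recipient, donor),) if flow == FLOW_ADM else ()
    return _enumerate_space([_initial_state(lumped)], mrca, mig_route, reach)


@lru_cache(maxsize=None)
def _ancestral_space(lumped: bool) -> EpochSpace:
    mrca = _MRCA_LUM if lumped else _MRCA_LAB
    init = _initial_state(lumped, deme_v="A", deme_b="A")
    return _enumerate_space([init], mrca, None, ())


@lru_cache(maxsize=None)
def _split_map(flow: str, donor: str | None, lumped: bool) -> np.ndarray:
    """Index map: pre-split state -> ancestral state after the deme merger."""
    pre = _presplit_space(flow, donor, lumped)
    anc = _ancestral_space(lumped)
    mrca = _MRCA_LUM if lumped else _MRCA_LAB
    out = np.empty(len(pre.states), dtype=np.int64)
    for i, s in enumerate(pre.states):
        mapped = _canon([("A", key) for _, key in s], mrca)
        out[i] = anc.index[mapped]
    return out


def build_state_space(model: DemographyModel, *, lumped: bool = False):
    """Enumerate the lineage-configuration state spaces of ``model``.

    Returns ``(presplit, ancestral, split_map)``.  With ``lumped=False``
    every lineage keeps its exact leaf subset (the ancestral single-deme
    epoch then has the 15 set partitions of four leaves as states); with
    ``lumped=True`` exchangeable leaves within a species are merged.
    """
    model.validate(require_bound=False)
    pre = _presplit_space(model.flow, model.donor, lumped)
    anc = _ancestral_space(lumped)
    return pre, anc, _split_map(model.flow, model.donor, lumped)


# ----------------------------------------------------------------------
# count augmentation
# ----------------------------------------------------------------------


@lru_cache(maxsize=8)
def _shift_ops(k_max: int):
    """Per-class count-increment operators on the (k_max+2)^4 count space.

    ``S_c = shift_c - diag(active_c)``: from any count vector whose class-c
    entry is at most ``k_max`` a class-c mutation moves probability one step
    up (the step from ``k_max`` lands in the lumped ``> k_max`` category,
    which is absorbing in that coordinate).
    """
    K = k_max + 2
    nc = K**4
    grid = np.indices((K, K, K, K)).reshape(4, nc)
    ops = []
    for c in range(4):
        stride = K ** (3 - c)
        active = grid[c] <= k_max
        rows = np.nonzero(active)[0]
        cols = rows + stride
        data = np.ones(rows.size)
        shift = sp.coo_matrix((data, (rows, cols)), shape=(nc, nc))
        diag = sp.coo_matrix((np.ones(rows.size), (rows, rows)), shape=(nc, nc))
        ops.append((shift - diag).tocsr())
    return nc, tuple(ops)


def _lineage_generator(space: EpochSpace, model: DemographyModel) -> sp.csr_matrix:
    scale = {
        "coal:V": 1.0 / model.c_v,
        "coal:B": 1.0 / model.c_b,
        "coal:A": 1.0 / model.c_anc,
        "mig": model.m if model.flow == FLOW_IM else 0.0,
    }
    n = len(space.states)
    rows, cols, data = [], [], []
    exit_rate = np.zeros(n)
    for i, j, tag, coeff in space.trans:
        r = coeff * scale[tag]
        if r == 0.0:
            continue
        rows.append(i)
        cols.append(j)
        data.append(r)
        exit_rate[i] += r
    rows.extend(range(n))
    cols.extend(range(n))
    data.extend(-exit_rate)
    return sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def _augmented_generator(
    space: EpochSpace, model: DemographyModel, theta: float, k_max: int
) -> sp.csr_matrix:
    nc, ops = _shift_ops(k_max)
    Q = sp.kron(_lineage_generator(space, model), sp.identity(nc, format="csr"))
    for c in range(4):
        w = theta * space.class_counts[:, c]
        if w.any():
            Q = Q + sp.kron(sp.diags(w), ops[c])
    return Q.tocsr()


def _pulse_matrix(space: EpochSpace, model: DemographyModel) -> sp.csr_matrix:
    """Stochastic matrix of the admixture pulse on lineage states.

    Backwards in time, each lineage in the forward-recipient deme
    independently jumps to the donor deme with probability ``f``.
    """
    f = model.f
    rec, don = model.recipient, model.donor
    mrca = space.states[space.mrca_idx]
    n = len(space.states)
    P = sp.lil_matrix((n, n))
    for i, s in enumerate(space.states):
        lin = list(s)
        movable = [a for a, (deme, _) in enumerate(lin) if deme == rec]
        if not movable or s == mrca:
            P[i, i] = 1.0
            continue
        for bits in range(1 << len(movable)):
            prob = 1.0
            moved = list(lin)
            for k, a in enumerate(movable):
                if bits >> k & 1:
                    prob *= f
                    moved[a] = (don, lin[a][1])
                else:
                    prob *= 1.0 - f
            if prob == 0.0:
                continue
            j = space.index[_canon(moved, mrca)]
            P[i, j] += prob
    return P.tocsr()


# ----------------------------------------------------------------------
# the table
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class ConfigProbabilityTable:
    """Probabilities of every truncated configuration under one model.

    ``table`` has shape ``(k_max + 2,) * 4`` with axes ordered
    (het_b, het_v, shared_het, fixed_diff); index ``k_max + 1`` along an
    axis is the lumped ``count > k_max`` category.
    """

    table: np.ndarray
    k_max: int
    theta_block: float
    model: DemographyModel

    @property
    def total(self) -> float:
        return float(self.table.sum())

    def prob(self, config) -> float:
        """Probability of a configuration; counts above ``k_max`` address
        the lumped overflow category of their class."""
        return float(self.table[self.cell(config)])

    def cell(self, config) -> tuple[int, int, int, int]:
        if len(config) != 4 or any(k < 0 for k in config):
            raise ValueError(f"invalid configuration {config!r}")
        return tuple(min(int(k), self.k_max + 1) for k in config)

    def to_tsv(self, path) -> None:
        K = self.k_max + 2
        with open(path, "w") as fh:
            fh.write("het_b\thet_v\tshared_het\tfixed_diff\tprobability\n")
            for idx in np.ndindex((K,) * 4):
                labels = [
                    (f">{self.k_max}" if k == self.k_max + 1 else str(k)) for k in idx
                ]
                fh.write("\t".join(labels) + f"\t{self.table[idx]:.12e}\n")


def config_distribution(
    model: DemographyModel,
    theta_block: float,
    k_max: int = 3,
    *,
    lumped: bool = True,
) -> ConfigProbabilityTable:
    """Compute the full configuration-probability table analytically.

    The table covers counts ``0..k_max`` per class plus a lumped
    ``> k_max`` category and sums to one (up to sparse solver tolerance).
    """
    model.validate()
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    if not theta_block > 0:
        raise ValueError("theta_block must be > 0")

    nc, _ = _shift_ops(k_max)
    anc = _ancestral_space(lumped)
    n_anc = len(anc.states)

    if model.t_split > 0.0:
        pre = _presplit_space(model.flow, model.donor, lumped)
        smap = _split_map(model.flow, model.donor, lumped)
        n_pre = len(pre.states)
        Q = _augmented_generator(pre, model, theta_block, k_max)
        p = np.zeros(n_pre * nc)
        p[pre.index[_initial_state(lumped)] * nc] = 1.0
        A = Q.T.tocsr()
        if model.flow == FLOW_ADM:
            if model.t_adm > 0.0:
                p = expm_multiply(A * model.t_adm, p)
            P_pulse = _pulse_matrix(pre, model)
            p = sp.kron(P_pulse.T, sp.identity(nc, format="csr")).dot(p)
            rest = model.t_split - model.t_adm
            if rest > 0.0:
                p = expm_multiply(A * rest, p)
        else:
            p = expm_multiply(A * model.t_split, p)
        # deme merger: aggregate pre-split states onto ancestral states
        P2 = np.zeros((n_anc, nc))
        np.add.at(P2, smap, p.reshape(n_pre, nc))
    else:
        P2 = np.zeros((n_anc, nc))
        P2[anc.index[_initial_state(lumped, "A", "A")], 0] = 1.0

    # absorbing ancestral epoch: exact linear solve for the count
    # distribution at full coalescence
    transient = [i for i in range(n_anc) if i != anc.mrca_idx]
    t_index = {i: k for k, i in enumerate(transient)}
    n_t = len(transient)

    scale_a = 1.0 / model.c_anc
    rows, cols, data = [], [], []
    b_rows, b_data = [], []
    exit_rate = np.zeros(n_t)
    for i, j, tag, coeff in anc.trans:
        r = coeff * scale_a
        ti = t_index[i]
        exit_rate[ti] += r
        if j == anc.mrca_idx:
            b_rows.append(ti)
            b_data.append(r)
        else:
            rows.append(ti)
            cols.append(t_index[j])
            data.append(r)
    rows.extend(range(n_t))
    cols.extend(range(n_t))
    data.extend(-exit_rate)
    A_lin = sp.coo_matrix((data, (rows, cols)), shape=(n_t, n_t)).tocsr()
    B_lin = sp.coo_matrix(
        (b_data, (b_rows, np.zeros(len(b_rows), dtype=int))), shape=(n_t, 1)
    ).tocsr()

    nc_, ops = _shift_ops(k_max)
    A_aug = sp.kron(A_lin, sp.identity(nc, format="csr"))
    for c in range(4):
        w = theta_block * anc.class_counts[transient, c]
        if w.any():
            A_aug = A_aug + sp.kron(sp.diags(w), ops[c])
    B_aug = sp.kron(B_lin, sp.identity(nc, format="csr")).tocsr()

    p_trans = P2[transient].reshape(n_t * nc)
    lu = splu((-A_aug.T).tocsc())
    x = lu.solve(p_trans)
    result = B_aug.T.dot(x) + P2[anc.mrca_idx]

    neg = result.min()
    if neg < -NEG_TOL:
        raise ArithmeticError(
            f"negative configuration probability {neg:.3e} (model "
            f"{model.model_id}, theta={theta_block}): numerical failure"
        )
    result = np.clip(result, 0.0, None)
    table = result.reshape((k_max + 2,) * 4)
    tot = table.sum()
    if not math.isfinite(tot) or abs(tot - 1.0) > 1e-6:
        raise ArithmeticError(
            f"configuration table does not normalise (total={tot!r})"
        )
    return ConfigProbabilityTable(
        table=table, k_max=k_max, theta_block=theta_block, model=model
    )


def config_probability(
    model: DemographyModel,
    theta_block: float,
    config,
    k_max: int = 3,
    *,
    lumped: bool = True,
) -> float:
    """Analytic probability of one configuration.

    Counts above ``k_max`` address the lumped overflow category of their
    class (``P(count > k_max)`` jointly with the other entries).
    """
    tab = config_distribution(model, theta_block, k_max, lumped=lumped)
    return tab.prob(config)


# ----------------------------------------------------------------------
# Monte-Carlo oracle
# ----------------------------------------------------------------------


def _mc_factors(taus: np.ndarray, theta: float, config, k_max: int) -> np.ndarray:
    """Per-simulation probability of ``config`` given branch lengths.

    Rao-Blackwellised: conditional on the genealogy the four class counts
    are independent Poissons, so the conditional probability is a product
    of pmf terms (or survival terms for lumped overflow entries).
    """
    w = np.ones(taus.shape[0])
    for c, k in enumerate(config):
        lam = theta * taus[:, c]
        if k > k_max:
            w = w * poisson.sf(k_max, lam)
        else:
            w = w * poisson.pmf(k, lam)
    return w


def mc_config_probability(
    model: DemographyModel,
    theta_block: float,
    config,
    n_sims: int,
    seed: int = 0,
    k_max: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of a configuration probability with its SE.

    Averages the conditional (given-genealogy) probability over ``n_sims``
    simulated genealogies; unbiased, deterministic given ``seed``.  When
    ``k_max`` is given, counts above it are treated as the lumped overflow
    category, matching :func:`config_distribution`.
    """
    from .simulate import simulate_branch_lengths

    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if k_max is None:
        k_max = max(config)
    taus = simulate_branch_lengths(model, n_sims, seed)
    w = _mc_factors(taus, theta_block, config, k_max)
    est = float(w.mean())
    se = float(w.std(ddof=1) / math.sqrt(n_sims)) if n_sims > 1 else 0.0
    return est, se


def mc_config_table(
    model: DemographyModel,
    theta_block: float,
    k_max: int,
    n_sims: int,
    seed: int = 0,
    taus: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo estimate of the full truncated table and per-cell SEs.

    All cells are estimated from the same genealogy sample, so estimates
    are correlated across cells but individually unbiased.
    """
    from .simulate import simulate_branch_lengths

    if taus is None:
        taus = simulate_branch_lengths(model, n_sims, seed)
    n = taus.shape[0]
    K = k_max + 2
    # per-class factor matrix: factors[c][k] over sims
    factors = np.empty((4, K, n))
    for c in range(4):
        lam = theta_block * taus[:, c]
        for k in range(k_max + 1):
            factors[c, k] = poisson.pmf(k, lam)
        factors[c, k_max + 1] = poisson.sf(k_max, lam)
    est = np.empty((K,) * 4)
    se = np.empty((K,) * 4)
    for idx in np.ndindex((K,) * 4):
        w = factors[0, idx[0]] * factors[1, idx[1]]
        w *= factors[2, idx[2]]
        w *= factors[3, idx[3]]
        est[idx] = w.mean()
        se[idx] = w.std(ddof=1) / math.sqrt(n)
    return est, se


# ----------------------------------------------------------------------
# composite likelihood
# ----------------------------------------------------------------------


def composite_loglik(tally, model: DemographyModel, theta_block: float, k_max: int = 3) -> float:
    """Composite log-likelihood of a bSFS tally under ``model``.

    ``lnCL = sum_config n_config * ln P(config)`` with per-block
    probabilities from :func:`config_distribution`; configurations with
    counts above ``k_max`` use their lumped overflow cells.  Probabilities
    are floored at :data:`PROB_FLOOR` (with a warning) so the result is
    always finite.
    """
    counts = getattr(tally, "counts", tally)
    if not counts:
        raise ValueError("empty tally")
    tab = config_distribution(model, theta_block, k_max)
    return tally_loglik(counts, tab)


def tally_loglik(counts: dict, tab: ConfigProbabilityTable) -> float:
    """lnCL of a configuration->count mapping against a precomputed table."""
    flat = tab.table.reshape(-1)
    K = tab.k_max + 2
    idx = np.empty(len(counts), dtype=np.int64)
    n = np.empty(len(counts))
    for r, (config, count) in enumerate(counts.items()):
        c = tab.cell(config)
        idx[r] = ((c[0] * K + c[1]) * K + c[2]) * K + c[3]
        n[r] = count
    p = flat[idx]
    if (p < PROB_FLOOR).any():
        logger.warning(
            "%d configuration(s) floored at %g in lnCL", int((p < PROB_FLOOR).sum()), PROB_FLOOR
        )
        p = np.maximum(p, PROB_FLOOR)
    return float(n @ np.log(p))
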