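"""First-order kinetic model of the kynurenine pathway (KP).

Tryptophan (Trp) catabolism: Trp → KYN; KYN branches to kynurenic acid (KA,
via KAT), anthranilic acid (AA, via KYNU) and 3-hydroxykynurenine (HK, via
KMO); HK branches to xanthurenic acid (XA, via KAT) and 3-hydroxyanthranilic
acid (HAA, via KYNU); HAA → quinolinic acid (QUIN, via 3HAO). Every reaction
is enzymatic Michaelis–Menten operating far below saturation ([S] ≪ K_M), so
v ≈ (k_cat/K_M)·[E]·[S] = k·[S]: the system is linear. Trp is a clamped
boundary driver (dietary input); terminal species (KA, AA, XA, QUIN) carry a
first-order clearance so steady states exist.

Steady states follow from mass balance, e.g.

    KYNss = k_TDO/IDO·Trp / (k_KAT1 + k_KYNU1 + k_KMO)
    HKss  = k_KMO·KYNss / (k_KAT2 + k_KYNU2)

so HKss ∝ k_KMO/(k_KAT1+k_KYNU1+k_KMO)·Trp: when k_KMO ≫ k_KAT1+k_KYNU1 the
HK level is insensitive to k_KMO while KYN still scales as its inverse —
the mechanism by which a KMO-activity variant shifts kynurenine but not
3-hydroxykynurenine. With human-derived constants (k_KMO = 22,
k_KYNU1 = 0.46, k_KAT1 = 2.08 s⁻¹ mM⁻¹) doubling k_KMO moves HKss by ~5%
but KYNss by ~47%.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp

__all__ = [
    "KP_SPECIES",
    "KPParameters",
    "KPState",
    "KPSteadyState",
    "HUMAN_CONSTANTS",
    "kp_rhs",
    "analytic_steady_state",
    "integrate_to_steady_state",
    "hk_equivalence_check",
    "group_compare_wilcoxon",
    "WilcoxonResult",
    "EquivalenceReport",
]

KP_SPECIES = ("Trp", "KYN", "HK", "KA", "AA", "XA", "HAA", "QUIN")
_TERMINAL = ("KA", "AA", "XA", "QUIN")


@dataclass
class KPParameters:
    """First-order rate constants (s⁻¹ mM⁻¹ scale with enzyme level folded
    in; only ratios matter for steady-state concentration ratios)."""

    k_tdo_ido: float = 1.0  # Trp -> KYN
    k_kat1: float = 2.08  # KYN -> KA
    k_kynu1: float = 0.46  # KYN -> AA
    k_kmo: float = 22.0  # KYN -> HK
    k_kat2: float = 1.0  # HK -> XA
    k_kynu2: float = 1.0  # HK -> HAA
    k_3hao: float = 1.0  # HAA -> QUIN
    k_clear: dict = field(default_factory=lambda: {s: 1.0 for s in _TERMINAL})

    def __post_init__(self) -> None:
        if isinstance(self.k_clear, (int, float)):
            self.k_clear = {s: float(self.k_clear) for s in _TERMINAL}
        for name in ("k_tdo_ido", "k_kat1", "k_kynu1", "k_kmo", "k_kat2", "k_kynu2", "k_3hao"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.k_clear.values()):
            raise ValueError("clearance constants must be >= 0")


# k_cat/K_M values derived from human enzymes, used when porcine constants
# are unavailable; the KMO branch dominates KYN consumption.
HUMAN_CONSTANTS = KPParameters(k_kmo=22.0, k_kynu1=0.46, k_kat1=2.08)


@dataclass
class KPState:
    """Concentrations in mM; Trp is the clamped boundary value."""

    Trp: float = 0.0
    KYN: float = 0.0
    HK: float = 0.0
    KA: float = 0.0
    AA: float = 0.0
    XA: float = 0.0
    HAA: float = 0.0
    QUIN: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in KP_SPECIES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "KPState":
        return cls(**dict(zip(KP_SPECIES, map(float, arr))))


@dataclass
class KPSteadyState:
    state: KPState
    residual: float  # max |d/dt| at the returned state
    method: str  # "analytic" | "integrated"


def kp_rhs(state: KPState, params: KPParameters) -> np.ndarray:
    """Time derivatives, ordered as KP_SPECIES; d[Trp]/dt forced to 0."""
    s = state.as_array()
    if np.any(s < 0):
        raise ValueError("negative concentration")
    trp, kyn, hk, ka, aa, xa, haa, quin = s
    p = params
    d = np.zeros(8)
    d[1] = p.k_tdo_ido * trp - (p.k_kat1 + p.k_kynu1 + p.k_kmo) * kyn
    d[2] = p.k_kmo * kyn - (p.k_kat2 + p.k_kynu2) * hk
    d[3] = p.k_kat1 * kyn - p.k_clear["KA"] * ka
    d[4] = p.k_kynu1 * kyn - p.k_clear["AA"] * aa
    d[5] = p.k_kat2 * hk - p.k_clear["XA"] * xa
    d[6] = p.k_kynu2 * hk - p.k_3hao * haa
    d[7] = p.k_3hao * haa - p.k_clear["QUIN"] * quin
    return d


def analytic_steady_state(params: KPParameters, trp: float) -> KPSteadyState:
    """Closed-form steady state of the linear system at clamped [Trp]."""
    p = params
    if trp < 0:
        raise ValueError("Trp must be >= 0")
    kyn_out = p.k_kat1 + p.k_kynu1 + p.k_kmo
    hk_out = p.k_kat2 + p.k_kynu2
    if kyn_out <= 0 and p.k_tdo_ido * trp > 0:
        raise ValueError("zero total consumption for KYN: no steady state")
    kyn = p.k_tdo_ido * trp / kyn_out if kyn_out > 0 else 0.0
    if p.k_kmo * kyn > 0 and hk_out <= 0:
        raise ValueError("zero total consumption for HK: no steady state")
    hk = p.k_kmo * kyn / hk_out if p.k_kmo * kyn > 0 else 0.0
    if p.k_kynu2 * hk > 0 and p.k_3hao <= 0:
        raise ValueError("zero total consumption for HAA: no steady state")
    haa = p.k_kynu2 * hk / p.k_3hao if p.k_kynu2 * hk > 0 else 0.0

    def cleared(production, species):
        if production == 0:
            return 0.0
        kc = p.k_clear[species]
        if kc <= 0:
            raise ValueError(f"clearance of {species} is zero: no steady state")
        return production / kc

    state = KPState(
        Trp=trp,
        KYN=kyn,
        HK=hk,
        HAA=haa,
        KA=cleared(p.k_kat1 * kyn, "KA"),
        AA=cleared(p.k_kynu1 * kyn, "AA"),
        XA=cleared(p.k_kat2 * hk, "XA"),
        QUIN=cleared(p.k_3hao * haa, "QUIN"),
    )
    resid = float(np.max(np.abs(kp_rhs(state, params))))
    return KPSteadyState(state=state, residual=resid, method="analytic")


def integrate_to_steady_state(
    params: KPParameters,
    trp: float,
    state0: Optional[KPState] = None,
    tol: float = 1e-10,
    max_time: float = 1e7,
) -> KPSteadyState:
    """Numeric oracle: stiff-safe integration until max |d/dt| < tol."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    state = state0 if state0 is not None else KPState()
    state = replace(state, Trp=trp)
    y = state.as_array()

    def rhs(_t, yv):
        d = kp_rhs(KPState.from_array(np.maximum(yv, 0.0)), params)
        d[0] = 0.0
        return d

    t_span = 1.0
    total = 0.0
    while total < max_time:
        if np.max(np.abs(rhs(0.0, y))) < tol:
            return KPSteadyState(
                state=KPState.from_array(y),
                residual=float(np.max(np.abs(rhs(0.0, y)))),
                method="integrated",
            )
        sol = solve_ivp(rhs, (0.0, t_span), y, method="LSODA", rtol=1e-12, atol=1e-14)
        y = np.maximum(sol.y[:, -1], 0.0)
        total += t_span
        t_span *= 4.0
    raise RuntimeError(f"no steady state within t = {max_time}")


@dataclass
class EquivalenceReport:
    hk_ss: tuple[float, float]
    kyn_ss: tuple[float, float]
    hk_relative_change: float
    kyn_relative_change: float
    sensitivity: float  # d log HKss / d log k_KMO at the first parameter set
    near_equal: bool  # |ΔHK|/HK below the tolerance


def hk_equivalence_check(
    params_g: KPParameters,
    params_a: KPParameters,
    trp: float = 1.0,
    rel_tol: float = 0.10,
) -> EquivalenceReport:
    """Compare HK steady states for two parameter sets differing only in
    k_KMO (two KMO genotypes).

    HKss ∝ k_KMO/(k_KAT1+k_KYNU1+k_KMO), so the two genotypes share the HK
    level iff k_KMO ≫ k_KAT1+k_KYNU1 for both. The log-sensitivity of HKss
    to k_KMO is (k_KAT1+k_KYNU1)/(k_KAT1+k_KYNU1+k_KMO).
    """
    for name in ("k_tdo_ido", "k_kat1", "k_kynu1", "k_kat2", "k_kynu2", "k_3hao"):
        if getattr(params_g, name) != getattr(params_a, name):
            raise ValueError(f"parameter sets differ outside k_KMO: {name}")
    if params_g.k_clear != params_a.k_clear:
        raise ValueError("parameter sets differ outside k_KMO: k_clear")

    ss_g = analytic_steady_state(params_g, trp).state
    ss_a = analytic_steady_state(params_a, trp).state
    hk_rel = abs(ss_a.HK - ss_g.HK) / max(ss_g.HK, np.finfo(float).tiny)
    kyn_rel = abs(ss_a.KYN - ss_g.KYN) / max(ss_g.KYN, np.finfo(float).tiny)
    branch = params_g.k_kat1 + params_g.k_kynu1
    sens = branch / (branch + params_g.k_kmo)
    return EquivalenceReport(
        hk_ss=(ss_g.HK, ss_a.HK),
        kyn_ss=(ss_g.KYN, ss_a.KYN),
        hk_relative_change=float(hk_rel),
        kyn_relative_change=float(kyn_rel),
        sensitivity=float(sens),
        near_equal=bool(hk_rel < rel_tol),
    )


@dataclass
class WilcoxonResult:
    statistic: float
    pvalue: float
    method: str  # "exact" | "asymptotic"
    flag: str = ""


def group_compare_wilcoxon(cohort_table, metabolite: str, group_labels) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) comparison of one KP
    metabolite between two groups.

    ``group_labels`` is either a column name of ``cohort_table`` or a
    sequence of per-row labels with exactly two levels. Exact distribution
    for min(n1, n2) ≤ 12 without ties; normal approximation with tie
    correction otherwise.
    """
    if isinstance(group_labels, str):
        labels = cohort_table[group_labels]
    else:
        labels = np.asarray(group_labels)
    values = np.asarray(cohort_table[metabolite], dtype=float)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    x = values[np.asarray(labels) == levels[0]]
    y = values[np.asarray(labels) == levels[1]]
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each group needs at least one observation")
    if np.all(values == values[0]):
        return WilcoxonResult(statistic=float(len(x) * len(y) / 2), pvalue=1.0,
                              method="degenerate", flag="all-tied")
    has_ties = len(np.unique(values)) < len(values)
    use_exact = min(len(x), len(y)) <= 12 and not has_ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if use_exact else "asymptotic")
    return WilcoxonResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        method="exact" if use_exact else "asymptotic",
    )
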