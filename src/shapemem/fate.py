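"""Delta-Notch lateral inhibition between the two daughter cells.

After division the daughters engage in mutual lateral inhibition: a cell's
Delta activates Notch in its sister, and high Notch represses the cell's
own Delta.  With activities per daughter the dynamics are the classic
two-cell lateral-inhibition system

    d Not / dt = F(Del_nei) - Not
    d Del / dt = nu * (G(Not) - Del)

with the saturating activation F(x) = x^2 / (a + x^2) (F(0) = 0, monotone
increasing) and the inhibition G(x) = 1 / (1 + b x^2) (G(0) = 1, monotone
decreasing).  Only Delta-Notch interaction and decay enter; no other
factors.

The Delta activities are initialized from the yellow-particle partition,
``Del_ini = n / N_yellow`` per daughter, and Notch starts at zero.  The pair
is integrated with a fixed-step 4th-order Runge-Kutta scheme, one step per
mcs.  A daughter whose Notch exceeds 0.98 while its Delta falls below 0.02
commits to the V2b fate and the sister becomes V2a; the integration then
stops.  The default parameters (a = 0.01, b = 100) make the committed
states reachable: the V2b attractor sits at Not = F(1) = 1/(1 + a) > 0.98
and Del = G(F(1)) ~ 0.01 < 0.02, which requires a <= 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FateParams",
    "FateState",
    "initial_conditions",
    "step_lateral_inhibition",
    "resolve_fate",
    "verify_bistability",
]


@dataclass
class FateParams:
    """Parameters of the two-cell lateral-inhibition ODE."""

    a: float = 0.01            # half-saturation of Notch activation F
    b: float = 100.0           # inhibition strength of G
    nu: float = 1.0            # relaxation rate of Delta
    dt: float = 0.5            # ODE time advanced per mcs
    notch_threshold: float = 0.98
    delta_threshold: float = 0.02
    max_mcs: int = 500

    def __post_init__(self):
        if not (0 < self.notch_threshold < 1 and 0 < self.delta_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    def activation(self, x):
        """F: Delta of the neighbour -> Notch production. F(0)=0, increasing."""
        return x * x / (self.a + x * x)

    def inhibition(self, x):
        """G: own Notch -> Delta production. G(0)=1, decreasing."""
        return 1.0 / (1.0 + self.b * x * x)


@dataclass
class FateState:
    """Delta/Notch activities of the (+) and (-) daughters."""

    del_plus: float
    del_minus: float
    not_plus: float = 0.0
    not_minus: float = 0.0
    resolved: bool = False
    fate_plus: str = "unresolved"   # V2a | V2b | unresolved
    fate_minus: str = "unresolved"
    mcs_resolved: int | None = None
    flags: list = field(default_factory=list)

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.del_plus, self.not_plus, self.del_minus, self.not_minus]
        )


def initial_conditions(n_plus: int, n_minus: int, n_yellow: int) -> FateState:
    """Delta initialized from the yellow-particle split; Notch starts at 0."""
    if n_plus + n_minus != n_yellow:
        raise ValueError("daughter particle counts must sum to the total")
    if n_yellow <= 0:
        raise ValueError("no yellow particles: fate is unresolvable")
    return FateState(
        del_plus=n_plus / n_yellow,
        del_minus=n_minus / n_yellow,
    )


def _rhs(y: np.ndarray, p: FateParams) -> np.ndarray:
    dp, np_, dm, nm = y
    return np.array(
        [
            p.nu * (p.inhibition(np_) - dp),
            p.activation(dm) - np_,
            p.nu * (p.inhibition(nm) - dm),
            p.activation(dp) - nm,
        ]
    )


def step_lateral_inhibition(
    state: FateState, params: FateParams, dt: float | None = None
) -> FateState:
    """Advance the coupled pair by one fixed-step RK4 step (clipped to >= 0)."""
    h = params.dt if dt is None else float(dt)
    if h <= 0:
        raise ValueError("dt must be > 0")
    y = state.as_vector()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite fate state")
    k1 = _rhs(y, params)
    k2 = _rhs(y + 0.5 * h * k1, params)
    k3 = _rhs(y + 0.5 * h * k2, params)
    k4 = _rhs(y + h * k3, params)
    y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    y = np.clip(y, 0.0, None)
    state.del_plus, state.not_plus, state.del_minus, state.not_minus = y
    return state


def _committed(delta: float, notch: float, p: FateParams) -> bool:
    return notch > p.notch_threshold and delta < p.delta_threshold


def resolve_fate(
    state: FateState,
    params: FateParams,
    rng: np.random.Generator | None = None,
    start_mcs: int = 0,
    record=None,
) -> FateState:
    """Integrate one ODE step per mcs until a daughter commits to V2b.

    The first daughter to pass ``Not > 0.98 and Del < 0.02`` is V2b and the
    sister V2a; if both cross in the same step, the daughter with the lower
    Delta takes V2b (flagged).  Exact ties left unresolved at ``max_mcs``
    are broken by a seeded coin flip (flagged); asymmetric states that fail
    to commit are reported unresolved (flagged).
    """
    if record is not None:
        record.append((start_mcs, state.del_plus, state.not_plus,
                       state.del_minus, state.not_minus))
    for mcs in range(start_mcs, params.max_mcs):
        step_lateral_inhibition(state, params)
        if record is not None:
            record.append((mcs + 1, state.del_plus, state.not_plus,
                           state.del_minus, state.not_minus))
        b_plus = _committed(state.del_plus, state.not_plus, params)
        b_minus = _committed(state.del_minus, state.not_minus, params)
        if b_plus and b_minus:
            state.flags.append("simultaneous_commit")
            b_plus = state.del_plus < state.del_minus
            b_minus = not b_plus
        if b_plus or b_minus:
            state.resolved = True
            state.mcs_resolved = mcs + 1
            state.fate_plus = "V2b" if b_plus else "V2a"
            state.fate_minus = "V2a" if b_plus else "V2b"
            return state
    if state.del_plus == state.del_minus:
        state.flags.append("exact_tie_coin_flip")
        if rng is None:
            rng = np.random.default_rng(0)
        plus_is_v2a = bool(rng.integers(0, 2))
        state.resolved = True
        state.mcs_resolved = None
        state.fate_plus = "V2a" if plus_is_v2a else "V2b"
        state.fate_minus = "V2b" if plus_is_v2a else "V2a"
    else:
        state.flags.append("unresolved_at_max_mcs")
    return state


def verify_bistability(
    params: FateParams, eps_grid=None, eps_required: float = 0.1
) -> dict:
    """Check that the parameters form a mutually exclusive binary switch.

    Scans initial Delta asymmetries (Del_ini = 0.5 +/- eps) and confirms
    that every asymmetry at or above some minimal ``eps_min`` resolves with
    the majority daughter V2a.  Raises when no scanned asymmetry resolves
    correctly, or when only extreme asymmetries do (``eps_min`` above
    ``eps_required``): a usable switch must flip for modest asymmetries,
    not merely when one daughter already starts at the committed state
    (e.g. frozen Delta, nu = 0, "resolves" from Del_ini = (1, 0) alone).
    """
    if eps_grid is None:
        eps_grid = (0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
    rows = []
    for eps in eps_grid:
        st = FateState(del_plus=0.5 + eps, del_minus=0.5 - eps)
        resolve_fate(st, params)
        ok = st.resolved and st.mcs_resolved is not None and st.fate_plus == "V2a"
        rows.append(
            {"eps": float(eps), "resolved": ok,
             "mcs_to_resolution": st.mcs_resolved if ok else None}
        )
    resolving = [r for r in rows if r["resolved"]]
    if not resolving:
        raise ValueError(
            "parameters rejected: no scanned asymmetry resolves into "
            "mutually exclusive fates"
        )
    eps_min = min(r["eps"] for r in resolving)
    if any(not r["resolved"] for r in rows if r["eps"] >= eps_min):
        raise ValueError(
            "parameters rejected: resolution is not monotone in the "
            "initial asymmetry"
        )
    if eps_min > eps_required:
        raise ValueError(
            f"parameters rejected: switch only flips for asymmetries >= "
            f"{eps_min}, required {eps_required}"
        )
    return {"eps_min": eps_min, "scan": rows}
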