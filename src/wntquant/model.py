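"""Unreduced Lee (2003) Wnt/beta-catenin ODE model and steady-state calibration.

The reaction network couples Wnt-dependent Dishevelled activation to the
axin/APC/GSK3beta degradation complex that phosphorylates beta-catenin and
commits it to proteasomal destruction.  Lee et al. (2003, PLoS Biology 1:e10)
reduced the four fast binding steps (axin+APC, beta-catenin binding to the
phosphorylated complex, beta-catenin+TCF, beta-catenin+APC) to equilibrium
relations; here the *complete* mass-action system of all 15 species is
integrated instead, with explicit forward/backward rates whose ratios equal
Lee's dissociation constants.

Calibration protocol
--------------------
Measured whole-cell totals enter as free species and are redistributed in two
phases: Phase A runs the network as a *closed* system (synthesis and
degradation fluxes off), Phase B continues from the Phase A steady state with
all fluxes on (*open* system).  Both phases use Wnt = 0.  The per-protein
ratio of initial to open-steady-state total concentration (I:SS) measures how
much of each measured protein the model retains; an open steady state reached
directly (skipping Phase A) is compared against the two-phase result to check
that the answer is independent of the redistribution path.

Units: concentrations in nM, time in minutes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "SPECIES",
    "PROTEIN_MEMBERSHIP",
    "ReactionParameters",
    "CalibrationInput",
    "SteadyStateResult",
    "RetentionReport",
    "load_parameters",
    "default_parameter_path",
    "derivatives",
    "totals_from_state",
    "initial_state_from_totals",
    "integrate_to_steady_state",
    "run_calibration",
    "simulate_transient",
]

# ---------------------------------------------------------------------------
# species roster (order fixed; indices used throughout)
# ---------------------------------------------------------------------------

#: The 15 species of the unreduced Lee model.  ``_p`` marks phosphorylated
#: forms; complexes are written in binding order.
SPECIES: tuple[str, ...] = (
    "dsh_inactive",            # x1
    "dsh_active",              # x2
    "apc_axin_gsk3_p",         # x3   APC*/axin*/GSK3 (phosphorylated complex)
    "apc_axin_gsk3",           # x4   APC/axin/GSK3
    "gsk3",                    # x5
    "apc_axin",                # x6
    "apc",                     # x7
    "bcat_apc_axin_gsk3_p",    # x8   beta-cat bound to APC*/axin*/GSK3
    "bcat_p_apc_axin_gsk3_p",  # x9   phospho-beta-cat still in the complex
    "bcat_p",                  # x10  free phospho-beta-catenin
    "bcat",                    # x11  free beta-catenin
    "axin",                    # x12
    "tcf",                     # x13
    "bcat_tcf",                # x14
    "bcat_apc",                # x15
)

_IX = {name: i for i, name in enumerate(SPECIES)}

#: Which species contain each conserved protein (stoichiometry 1 throughout).
PROTEIN_MEMBERSHIP: dict[str, tuple[str, ...]] = {
    "Dsh": ("dsh_inactive", "dsh_active"),
    "APC": (
        "apc_axin_gsk3_p", "apc_axin_gsk3", "apc_axin", "apc",
        "bcat_apc_axin_gsk3_p", "bcat_p_apc_axin_gsk3_p", "bcat_apc",
    ),
    "GSK3": (
        "apc_axin_gsk3_p", "apc_axin_gsk3", "gsk3",
        "bcat_apc_axin_gsk3_p", "bcat_p_apc_axin_gsk3_p",
    ),
    "axin": (
        "apc_axin_gsk3_p", "apc_axin_gsk3", "apc_axin",
        "bcat_apc_axin_gsk3_p", "bcat_p_apc_axin_gsk3_p", "axin",
    ),
    "beta_catenin": (
        "bcat_apc_axin_gsk3_p", "bcat_p_apc_axin_gsk3_p",
        "bcat_p", "bcat", "bcat_tcf", "bcat_apc",
    ),
    "TCF": ("tcf", "bcat_tcf"),
}

_MEMBERSHIP_MATRIX = np.zeros((len(PROTEIN_MEMBERSHIP), len(SPECIES)))
for _r, (_prot, _members) in enumerate(PROTEIN_MEMBERSHIP.items()):
    for _m in _members:
        _MEMBERSHIP_MATRIX[_r, _IX[_m]] = 1.0

_RATE_SYMBOLS = (
    "k1", "k2", "k3", "k4", "k5", "k6", "k_6", "k9", "k10", "k11",
    "v12", "k13", "v14", "k15", "K7", "K8", "K16", "K17",
    "binding_forward_rate",
)
_TOTAL_SYMBOLS = ("Dsh", "TCF", "GSK3", "APC")

# negative excursions smaller than this (nM) are solver dust and are clamped
_NEGATIVE_DUST = 1e-9


class ParameterError(ValueError):
    """Raised when a parameter file is incomplete or inconsistent."""


@dataclass(frozen=True)
class ReactionParameters:
    """Rate constants, fluxes and conserved totals of the Lee network.

    The four rapid binding steps carry an explicit common forward rate
    (``binding_forward_rate``, /nM/min); each reverse rate is that forward
    rate times the corresponding dissociation constant, so the pairs are
    consistent with Lee's K7, K8, K16 and K17 by construction.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k_6: float
    k9: float
    k10: float
    k11: float
    v12: float
    k13: float
    v14: float
    k15: float
    K7: float
    K8: float
    K16: float
    K17: float
    binding_forward_rate: float
    totals: Mapping[str, float] = field(default_factory=dict)
    xenopus_initial: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym in _RATE_SYMBOLS:
            value = getattr(self, sym)
            if value < 0:
                raise ParameterError(f"rate constant {sym} must be >= 0, got {value}")
        for name in _TOTAL_SYMBOLS:
            if name not in self.totals:
                raise ParameterError(f"conserved total for {name} missing")
            if self.totals[name] < 0:
                raise ParameterError(f"total {name} must be >= 0")

    # reverse rates of the fast binding steps
    @property
    def k7f(self) -> float:
        return self.binding_forward_rate

    @property
    def k7r(self) -> float:
        return self.binding_forward_rate * self.K7

    @property
    def k8f(self) -> float:
        return self.binding_forward_rate

    @property
    def k8r(self) -> float:
        return self.binding_forward_rate * self.K8

    @property
    def k16f(self) -> float:
        return self.binding_forward_rate

    @property
    def k16r(self) -> float:
        return self.binding_forward_rate * self.K16

    @property
    def k17f(self) -> float:
        return self.binding_forward_rate

    @property
    def k17r(self) -> float:
        return self.binding_forward_rate * self.K17


def default_parameter_path() -> Path:
    """Path of the packaged Lee (2003) reference parameter file."""
    return Path(str(resources.files("wntquant").joinpath("data/lee2003.yaml")))


def load_parameters(source: str | Path | Mapping | None = None) -> ReactionParameters:
    """Load and validate :class:`ReactionParameters` from YAML or a mapping.

    With ``source=None`` the packaged Lee (2003) reference set is used.
    Missing or negative symbols raise :class:`ParameterError` naming the
    offending symbol; unknown extra symbols are reported as well.
    """
    if source is None:
        source = default_parameter_path()
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError("parameter source must be a mapping")

    missing = [s for s in _RATE_SYMBOLS if s not in raw]
    if missing:
        raise ParameterError(f"{missing[0]} missing from parameter file")
    totals = raw.get("totals")
    if not isinstance(totals, dict):
        raise ParameterError("totals missing from parameter file")
    extra = set(raw) - set(_RATE_SYMBOLS) - {"totals", "xenopus_initial"}
    if extra:
        raise ParameterError(f"unknown parameter symbols: {sorted(extra)}")
    return ReactionParameters(
        **{s: float(raw[s]) for s in _RATE_SYMBOLS},
        totals={k: float(v) for k, v in totals.items()},
        xenopus_initial={k: float(v) for k, v in raw.get("xenopus_initial", {}).items()},
    )


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def derivatives(
    state: np.ndarray,
    params: ReactionParameters,
    mode: str = "open",
    w: float = 0.0,
) -> np.ndarray:
    """Mass-action time derivatives (nM/min) of all 15 species.

    ``mode='closed'`` switches off the synthesis fluxes (v12, v14) and all
    degradation steps (k11, k13, k15), making every protein moiety an exact
    invariant of the dynamics.  ``w`` is the dimensionless Wnt activity and
    enters only the Dishevelled activation step.
    """
    if mode not in ("open", "closed"):
        raise ValueError(f"mode must be 'open' or 'closed', got {mode!r}")
    p = params
    x = np.asarray(state, dtype=float)

    v1 = p.k1 * w * x[0]
    v2 = p.k2 * x[1]
    v3 = p.k3 * x[1] * x[3]
    v4 = p.k4 * x[3]
    v5 = p.k5 * x[2]
    v6 = p.k6 * x[5] * x[4] - p.k_6 * x[3]
    v7 = p.k7f * x[11] * x[6] - p.k7r * x[5]
    v8 = p.k8f * x[10] * x[2] - p.k8r * x[7]
    v9 = p.k9 * x[7]
    v10 = p.k10 * x[8]
    v16 = p.k16f * x[10] * x[12] - p.k16r * x[13]
    v17 = p.k17f * x[10] * x[6] - p.k17r * x[14]

    if mode == "open":
        v11 = p.k11 * x[9]
        v12 = p.v12
        v13 = p.k13 * x[10]
        v14 = p.v14
        v15 = p.k15 * x[11]
    else:
        v11 = v12 = v13 = v14 = v15 = 0.0

    dx = np.empty_like(x)
    dx[0] = -v1 + v2
    dx[1] = v1 - v2
    dx[2] = v4 - v5 - v8 + v10
    dx[3] = -v3 - v4 + v5 + v6
    dx[4] = v3 - v6
    dx[5] = v3 + v7 - v6
    dx[6] = -v7 - v17
    dx[7] = v8 - v9
    dx[8] = v9 - v10
    dx[9] = v10 - v11
    dx[10] = v12 - v13 - v8 - v16 - v17
    dx[11] = v14 - v15 - v7
    dx[12] = -v16
    dx[13] = v16
    dx[14] = v17
    return dx


def totals_from_state(state: np.ndarray | Mapping[str, float]) -> dict[str, float]:
    """Total concentration of each protein: free plus every complex containing it."""
    if isinstance(state, Mapping):
        x = np.array([state.get(name, 0.0) for name in SPECIES], dtype=float)
    else:
        x = np.asarray(state, dtype=float)
    sums = _MEMBERSHIP_MATRIX @ x
    return dict(zip(PROTEIN_MEMBERSHIP, sums))


@dataclass(frozen=True)
class CalibrationInput:
    """Measured (or assumed) initial total concentrations, nM."""

    beta_catenin: float
    axin: float
    apc: float
    gsk3: float
    dsh: float
    tcf: float
    name: str = ""
    dsh_tcf_assumed: bool = True  # Dsh/TCF rarely measured; flagged in reports

    def __post_init__(self) -> None:
        for f in ("beta_catenin", "axin", "apc", "gsk3", "dsh", "tcf"):
            if getattr(self, f) < 0:
                raise ValueError(f"total {f} must be >= 0")


def initial_state_from_totals(inp: CalibrationInput) -> np.ndarray:
    """Place every measured total in its free species (no complexes formed)."""
    x = np.zeros(len(SPECIES))
    x[_IX["dsh_inactive"]] = inp.dsh
    x[_IX["gsk3"]] = inp.gsk3
    x[_IX["apc"]] = inp.apc
    x[_IX["bcat"]] = inp.beta_catenin
    x[_IX["axin"]] = inp.axin
    x[_IX["tcf"]] = inp.tcf
    return x


@dataclass
class SteadyStateResult:
    state: np.ndarray
    residual: float          # max |dx/dt| over species, nM/min
    converged: bool
    mode: str
    t_final: float           # integrated time, min

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SPECIES, self.state))


def _clamp_dust(x: np.ndarray) -> np.ndarray:
    """Zero out tiny negative solver excursions; larger negatives are errors."""
    worst = x.min(initial=0.0)
    if worst < -_NEGATIVE_DUST:
        raise RuntimeError(
            f"solver produced a negative concentration ({worst:.3e} nM) beyond "
            "numerical dust; reduce tolerances"
        )
    out = x.copy()
    out[out < 0] = 0.0
    return out


# moieties with no synthesis/degradation flux stay conserved even in open mode
_CONSERVED = {
    "closed": ("Dsh", "APC", "GSK3", "axin", "beta_catenin", "TCF"),
    "open": ("Dsh", "APC", "GSK3", "TCF"),
}


def integrate_to_steady_state(
    state0: Sequence[float] | np.ndarray,
    params: ReactionParameters,
    mode: str = "open",
    w: float = 0.0,
    tol: float = 1e-10,
    t_max: float = 1e6,
    rtol: float = 1e-8,
    atol: float = 1e-11,
    refine_trigger: float = 1e-6,
) -> SteadyStateResult:
    """Integrate the stiff system until ``max |dx/dt| < tol`` (nM/min).

    Integration proceeds over geometrically expanding time windows with a
    stiff solver (LSODA).  Once the derivative norm falls below
    ``refine_trigger`` the state is polished by root-finding on the
    derivative function (Levenberg-Marquardt, which tolerates the rank
    deficiency introduced by the conservation laws); the refined state is
    accepted only if it reaches ``tol``, stays non-negative and preserves the
    mode's conserved totals, otherwise integration continues.
    Non-convergence at ``t_max`` is reported via the ``converged`` flag,
    never silently.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    rhs = lambda t, y: derivatives(y, params, mode=mode, w=w)
    conserved = _CONSERVED[mode]

    x = np.asarray(state0, dtype=float).copy()
    if x.shape != (len(SPECIES),):
        raise ValueError(f"state must have {len(SPECIES)} entries")
    t_now = 0.0
    window = 10.0
    residual = float(np.max(np.abs(rhs(0.0, x))))
    converged = residual < tol
    while not converged and t_now < t_max:
        t_end = min(t_now + window, t_max)
        # max_step bounded by the window: the solver's step-size control can
        # grow h without bound (and overflow) once the trajectory sits on the
        # steady state within a long window.
        max_step = max(1.0, window / 10.0)
        with warnings.catch_warnings():
            # LSODA emits a UserWarning when it stalls; the BDF retry below
            # handles that case.
            warnings.simplefilter("ignore", UserWarning)
            sol = solve_ivp(
                rhs, (t_now, t_end), x, method="LSODA", rtol=rtol, atol=atol,
                max_step=max_step, dense_output=False,
            )
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            # LSODA can stall on extreme stiffness (very fast binding rates);
            # retry the window with BDF before giving up.
            sol = solve_ivp(
                rhs, (t_now, t_end), x, method="BDF", rtol=rtol, atol=atol,
                max_step=max_step, dense_output=False,
            )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        if not np.all(np.isfinite(sol.y[:, -1])):  # pragma: no cover - defensive
            raise RuntimeError("ODE integration produced non-finite values")
        x = _clamp_dust(sol.y[:, -1])
        t_now = sol.t[-1]
        window *= 10.0
        residual = float(np.max(np.abs(rhs(t_now, x))))
        if residual < refine_trigger:
            x, residual = _refine_root(rhs, x, residual, conserved)
        converged = residual < tol
    return SteadyStateResult(
        state=x, residual=residual, converged=converged, mode=mode, t_final=t_now
    )


def _refine_root(
    rhs, x: np.ndarray, residual: float, conserved: Sequence[str]
) -> tuple[np.ndarray, float]:
    """Polish a near-steady state by LM root-finding on the derivative.

    Rejected (returning the input unchanged) if the root drifts off the
    conservation manifold, goes negative, or does not improve the residual.
    """
    totals_before = totals_from_state(x)
    try:
        sol = root(lambda y: rhs(0.0, y), x, method="lm", options={"xtol": 1e-14})
    except Exception:  # pragma: no cover - defensive
        return x, residual
    cand = sol.x
    if cand.min(initial=0.0) < -_NEGATIVE_DUST:
        return x, residual
    cand = _clamp_dust(cand)
    cand_res = float(np.max(np.abs(rhs(0.0, cand))))
    if cand_res >= residual:
        return x, residual
    totals_after = totals_from_state(cand)
    for prot in conserved:
        before = totals_before[prot]
        scale = max(abs(before), 1e-6)
        if abs(totals_after[prot] - before) > 1e-6 * scale:
            return x, residual  # refinement drifted off the conservation manifold
    return cand, cand_res


@dataclass
class RetentionReport:
    """Initial vs open-steady-state totals after the two-phase calibration."""

    name: str
    initial_totals: dict[str, float]        # nM
    steady_state_totals: dict[str, float]   # nM
    retention: dict[str, float]             # SS/initial, dimensionless
    free_axin: float                        # nM
    total_axin: float                       # nM
    pathway_independent: bool
    converged: bool
    phase_a: SteadyStateResult | None = None
    phase_b: SteadyStateResult | None = None
    direct_b: SteadyStateResult | None = None
    dsh_tcf_assumed: bool = True

    def retention_percent(self, protein: str = "beta_catenin") -> float:
        return 100.0 * self.retention[protein]

    def as_record(self) -> dict:
        rec: dict = {"name": self.name, "converged": self.converged,
                     "pathway_independent": self.pathway_independent,
                     "dsh_tcf_assumed": self.dsh_tcf_assumed,
                     "free_axin_nM": self.free_axin,
                     "total_axin_nM": self.total_axin}
        for prot in PROTEIN_MEMBERSHIP:
            rec[f"initial_{prot}_nM"] = self.initial_totals.get(prot)
            rec[f"ss_{prot}_nM"] = self.steady_state_totals.get(prot)
            r = self.retention.get(prot)
            rec[f"i_ss_{prot}"] = None if r is None else f"1:{r:.2f}"
        return rec


def run_calibration(
    inp: CalibrationInput,
    params: ReactionParameters | None = None,
    w: float = 0.0,
    tol: float = 1e-10,
    t_max: float = 1e6,
    path_independence_rtol: float = 1e-3,
) -> RetentionReport:
    """Two-phase steady-state redistribution of measured totals (Wnt off).

    Phase A distributes the free initial totals among the complexes in a
    closed system; Phase B continues from that state with all synthesis and
    degradation fluxes on.  A direct open-system run from the same initial
    state cross-checks that the final steady state does not depend on the
    path taken.
    """
    if params is None:
        params = load_parameters()
    x0 = initial_state_from_totals(inp)
    initial_totals = totals_from_state(x0)

    phase_a = integrate_to_steady_state(x0, params, mode="closed", w=w,
                                        tol=tol, t_max=t_max)
    phase_b = integrate_to_steady_state(phase_a.state, params, mode="open", w=w,
                                        tol=tol, t_max=t_max)
    direct_b = integrate_to_steady_state(x0, params, mode="open", w=w,
                                         tol=tol, t_max=t_max)

    converged = phase_a.converged and phase_b.converged
    ss_totals = totals_from_state(phase_b.state)
    retention: dict[str, float] = {}
    if converged:
        for prot, init in initial_totals.items():
            retention[prot] = ss_totals[prot] / init if init > 0 else math.nan
    else:  # pragma: no cover - signalled, not silent
        warnings.warn(f"calibration for {inp.name or 'input'} did not converge")

    independent = False
    if phase_b.converged and direct_b.converged:
        tot_two = np.array([ss_totals[p] for p in PROTEIN_MEMBERSHIP])
        tot_one = np.array(
            [totals_from_state(direct_b.state)[p] for p in PROTEIN_MEMBERSHIP]
        )
        scale = np.maximum(np.abs(tot_two), 1e-9)
        independent = bool(
            np.all(np.abs(tot_two - tot_one) / scale < path_independence_rtol)
        )

    return RetentionReport(
        name=inp.name,
        initial_totals=initial_totals,
        steady_state_totals=ss_totals,
        retention=retention,
        free_axin=float(phase_b.state[_IX["axin"]]),
        total_axin=float(ss_totals["axin"]),
        pathway_independent=independent,
        converged=converged,
        phase_a=phase_a,
        phase_b=phase_b,
        direct_b=direct_b,
        dsh_tcf_assumed=inp.dsh_tcf_assumed,
    )


def xenopus_input(params: ReactionParameters | None = None) -> CalibrationInput:
    """Reference Xenopus egg-extract totals (Lee 2003)."""
    if params is None:
        params = load_parameters()
    return CalibrationInput(
        beta_catenin=params.xenopus_initial["beta_catenin"],
        axin=params.xenopus_initial["axin"],
        apc=params.totals["APC"],
        gsk3=params.totals["GSK3"],
        dsh=params.totals["Dsh"],
        tcf=params.totals["TCF"],
        name="Xenopus",
        dsh_tcf_assumed=False,
    )


def simulate_transient(
    state0: Sequence[float] | np.ndarray,
    params: ReactionParameters,
    wnt_profile: Callable[[float], float] | float,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-12,
    warn_if_not_steady: bool = True,
) -> np.ndarray:
    """Time course of all species under a Wnt activity profile W(t).

    Returns an array of shape ``(len(t_grid), 15)``; the first row equals the
    initial state exactly.  ``wnt_profile`` may be a constant or a callable.
    """
    x0 = np.asarray(state0, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if callable(wnt_profile):
        wfun = wnt_profile
    else:
        wconst = float(wnt_profile)
        wfun = lambda t: wconst
    if warn_if_not_steady:
        res0 = float(np.max(np.abs(derivatives(x0, params, mode="open", w=0.0))))
        if res0 > 1e-6:
            warnings.warn(
                f"transient started from a non-steady state (residual {res0:.2e} nM/min)"
            )
    rhs = lambda t, y: derivatives(y, params, mode="open", w=wfun(t))
    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), x0, method="BDF", t_eval=t_grid,
        rtol=rtol, atol=atol,
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"transient integration failed: {sol.message}")
    out = sol.y.T.copy()
    out[0] = x0
    return out
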