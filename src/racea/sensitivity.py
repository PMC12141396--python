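"""One-way (tornado) and probabilistic sensitivity analysis.

Tornado: each named parameter is varied ±10% around its base value (both
arms re-run at the low and the high value) and the induced range of the
incremental net monetary benefit, NMB = WTP·ΔQ − ΔC, is recorded.  NMB is
used rather than the ICER because the base case is dominant and negative
ICERs cannot be ordered.  Parameters shared by both strategies (utility
coefficients, state-cost coefficients, HAQ improvements per response
category) are varied jointly in both arms; arm-specific parameters (drug
costs, response rates) are varied in their own arm.  Cumulative ACR response
rates are varied on the cumulative scale: moving e.g. the ACR50 rate
reallocates probability between the adjacent exclusive categories, keeping
the four-category split on the simplex.

PSA: Monte Carlo over the configured input distributions — gamma for costs
(shape/scale moment-matched to mean and SE), beta for utilities and single
probabilities, Dirichlet over the four response categories with
concentration equal to the observed category counts.  The cost-effectiveness
acceptability curve (CEAC) reports, at each willingness-to-pay value, the
fraction of draws with positive incremental NMB, all evaluated on the same
draw set.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .markov import ArmConfig, ModelConfig, icer, run_cea, summarize_trace, run_cohort

__all__ = [
    "TornadoEntry",
    "TornadoResult",
    "PSAResult",
    "get_parameter",
    "set_parameter",
    "one_way_tornado",
    "sample_psa_config",
    "run_psa",
]

_CUM_LEVELS = ("ACR20", "ACR50", "ACR70")


# ---------------------------------------------------------------------------
# parameter paths
# ---------------------------------------------------------------------------

def _cumulative(resp: Dict[str, float]) -> Dict[str, float]:
    return {
        "ACR70": resp["ACR70"],
        "ACR50": resp["ACR70"] + resp["ACR50"],
        "ACR20": resp["ACR70"] + resp["ACR50"] + resp["ACR20"],
    }


def _from_cumulative(cum: Dict[str, float]) -> Dict[str, float]:
    if not (0.0 <= cum["ACR70"] <= cum["ACR50"] <= cum["ACR20"] <= 1.0):
        raise ConfigurationError(
            f"cumulative response rates must be ordered within [0, 1]: {cum}"
        )
    return {
        "ACR70": cum["ACR70"],
        "ACR50": cum["ACR50"] - cum["ACR70"],
        "ACR20": cum["ACR20"] - cum["ACR50"],
        "NONE": 1.0 - cum["ACR20"],
    }


def _resolve(config: ModelConfig, path: str):
    """Resolve a dotted path to (owner object, attribute/key)."""
    parts = path.split(".")
    obj = config
    for i, part in enumerate(parts[:-1]):
        if isinstance(obj, dict):
            if part not in obj:
                raise ConfigurationError(f"unknown parameter path {path!r}")
            obj = obj[part]
        elif hasattr(obj, part):
            obj = getattr(obj, part)
        else:
            raise ConfigurationError(f"unknown parameter path {path!r}")
    return obj, parts[-1]


def get_parameter(config: ModelConfig, path: str) -> float:
    """Read a scalar model parameter by dotted path.

    Paths mirror the config structure (``arms.tof.drug_cost_per_cycle``,
    ``arms.ada.utility.intercept``); the virtual leaves ``acr20_rate``,
    ``acr50_rate`` and ``acr70_rate`` expose an arm's *cumulative* responder
    rates.
    """
    owner, leaf = _resolve(config, path)
    if leaf.endswith("_rate") and leaf[:-5].upper() in _CUM_LEVELS:
        if not isinstance(owner, ArmConfig):
            raise ConfigurationError(f"{path!r}: rates live on an arm")
        return _cumulative(owner.response)[leaf[:-5].upper()]
    if isinstance(owner, dict):
        if leaf not in owner:
            raise ConfigurationError(f"unknown parameter path {path!r}")
        return float(owner[leaf])
    if not hasattr(owner, leaf):
        raise ConfigurationError(f"unknown parameter path {path!r}")
    val = getattr(owner, leaf)
    if not np.isscalar(val):
        raise ConfigurationError(f"{path!r} is not a scalar parameter")
    return float(val)


def set_parameter(config: ModelConfig, path: str, value: float) -> None:
    """Set a scalar model parameter (in place) by dotted path.

    Probabilities are clamped to [0, 1] with a warning.  Setting a
    cumulative ``acrXX_rate`` reallocates mass between the adjacent
    exclusive categories (ACR20 trades with no-response).
    """
    owner, leaf = _resolve(config, path)
    if leaf.endswith("_rate") and leaf[:-5].upper() in _CUM_LEVELS:
        level = leaf[:-5].upper()
        cum = _cumulative(owner.response)
        lo = {"ACR70": 0.0, "ACR50": cum["ACR70"], "ACR20": cum["ACR50"]}[level]
        hi = {"ACR70": cum["ACR50"], "ACR50": cum["ACR20"], "ACR20": 1.0}[level]
        clamped = min(max(value, lo), hi)
        if clamped != value:
            warnings.warn(
                f"{path}: value {value:.4f} clamped to [{lo:.4f}, {hi:.4f}] "
                "to keep the response split on the simplex",
                stacklevel=2,
            )
        cum[level] = clamped
        owner.response = _from_cumulative(cum)
        return
    current = get_parameter(config, path)  # validates the path
    prob_like = (
        "probability" in leaf or leaf.endswith("_per_cycle_prob")
        or "withdrawal" in leaf or leaf == "mortality_per_cycle"
    )
    if prob_like and not (0.0 <= value <= 1.0):
        clamped = min(max(value, 0.0), 1.0)
        warnings.warn(f"{path}: probability {value:.4f} clamped to {clamped:.4f}",
                      stacklevel=2)
        value = clamped
    # frozen dataclass leaves (UtilityMap) are replaced wholesale
    if isinstance(owner, dict):
        owner[leaf] = value
        return
    try:
        setattr(owner, leaf, value)
    except AttributeError:
        from dataclasses import replace as _replace
        parts = path.split(".")
        parent, pleaf = _resolve(config, ".".join(parts[:-1]))
        new = _replace(owner, **{leaf: value})
        if isinstance(parent, dict):
            parent[pleaf] = new
        else:
            setattr(parent, pleaf, new)


def _expand(config: ModelConfig, path: str) -> List[str]:
    """``arms.*.x`` → one path per arm (varied jointly as one parameter)."""
    if ".*." in path:
        return [path.replace(".*.", f".{a}.") for a in config.arms]
    return [path]


# ---------------------------------------------------------------------------
# tornado
# ---------------------------------------------------------------------------

DEFAULT_TORNADO_PARAMETERS: Tuple[str, ...] = (
    "arms.tof.drug_cost_per_cycle",
    "arms.ada.drug_cost_per_cycle",
    "arms.tof.acr20_rate",
    "arms.tof.acr50_rate",
    "arms.tof.acr70_rate",
    "arms.ada.acr20_rate",
    "arms.ada.acr50_rate",
    "arms.ada.acr70_rate",
    "arms.*.palliative_drug_cost_per_cycle",
    "arms.*.state_cost_base_per_cycle",
    "arms.*.state_cost_per_haq_per_cycle",
    "arms.*.nonmedical_cost_per_cycle",
    "arms.*.indirect_cost_per_cycle",
    "arms.*.utility.intercept",
    "arms.*.utility.slope",
    "arms.*.delta_haq.ACR20",
    "arms.*.delta_haq.ACR50",
    "arms.*.delta_haq.ACR70",
    "arms.*.sae_disutility_per_cycle",
)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    base: float
    low: float
    high: float
    nmb_low: float
    nmb_high: float
    icer_low: Optional[float]
    icer_high: Optional[float]

    @property
    def range(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


@dataclass
class TornadoResult:
    base_nmb: float
    entries: List[TornadoEntry]  # sorted by descending range

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": e.parameter,
                    "base": e.base,
                    "low": e.low,
                    "high": e.high,
                    "nmb_low": e.nmb_low,
                    "nmb_high": e.nmb_high,
                    "range": e.range,
                }
                for e in self.entries
            ]
        )

    def ranked_parameters(self) -> List[str]:
        return [e.parameter for e in self.entries]


def _nmb(config: ModelConfig) -> Tuple[float, Optional[float]]:
    res = run_cea(config)
    inc = res.incremental
    nmb = config.wtp_per_qaly * inc.delta_qalys - inc.delta_cost
    return nmb, inc.icer


def one_way_tornado(
    config: ModelConfig,
    parameters: Sequence[str] = DEFAULT_TORNADO_PARAMETERS,
    rel_change: float = 0.10,
) -> TornadoResult:
    """±``rel_change`` one-way sensitivity of incremental NMB (TOF vs ADA)."""
    config.validate()
    base_nmb, _ = _nmb(config)
    entries = []
    for param in parameters:
        paths = _expand(config, param)
        base_vals = [get_parameter(config, p) for p in paths]
        outcomes = {}
        for tag, fac in (("low", 1 - rel_change), ("high", 1 + rel_change)):
            trial = copy.deepcopy(config)
            for p, v in zip(paths, base_vals):
                set_parameter(trial, p, v * fac)
            outcomes[tag] = _nmb(trial)
        entries.append(
            TornadoEntry(
                parameter=param,
                base=base_vals[0],
                low=base_vals[0] * (1 - rel_change),
                high=base_vals[0] * (1 + rel_change),
                nmb_low=outcomes["low"][0],
                nmb_high=outcomes["high"][0],
                icer_low=outcomes["low"][1],
                icer_high=outcomes["high"][1],
            )
        )
    entries.sort(key=lambda e: (-e.range, e.parameter))
    return TornadoResult(base_nmb=base_nmb, entries=entries)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAParameter:
    """One stochastic input: a path plus its sampling distribution.

    ``dist`` is ``gamma`` (costs; needs ``se`` or ``se_frac``) or ``beta``
    (utilities/probabilities; needs ``se``/``se_frac`` or ``events``/``n``).
    ``scale`` divides the value before beta sampling (for quantities on
    [0, scale] such as HAQ improvements).
    """

    path: str
    dist: str
    se: Optional[float] = None
    se_frac: Optional[float] = None
    events: Optional[float] = None
    n: Optional[float] = None
    scale: float = 1.0


def _se_of(p: PSAParameter, mean: float) -> float:
    if p.se is not None:
        se = p.se
    elif p.se_frac is not None:
        se = p.se_frac * abs(mean)
    elif p.events is not None and p.n:
        se = math.sqrt(max(p.events, 0.5) * (1 - p.events / p.n)) / p.n
    else:
        raise ConfigurationError(f"{p.path}: no dispersion given for PSA")
    if se < 0:
        raise ConfigurationError(f"{p.path}: PSA standard error must be >= 0")
    return se


def _draw_gamma(mean: float, se: float, rng: np.random.Generator) -> float:
    shape = (mean / se) ** 2
    scale = se**2 / mean
    return float(rng.gamma(shape, scale))


def _draw_beta(mean: float, se: float, rng: np.random.Generator) -> float:
    var = se**2
    if var >= mean * (1 - mean):
        raise ConfigurationError(
            f"beta moment matching impossible: se {se} too large for mean {mean}"
        )
    nu = mean * (1 - mean) / var - 1
    return float(rng.beta(mean * nu, (1 - mean) * nu))


def default_psa_parameters() -> List[PSAParameter]:
    """Stochastic inputs matching the packaged base-case configuration."""
    params: List[PSAParameter] = []
    for arm in ("tof", "ada"):
        params.append(PSAParameter(f"arms.{arm}.drug_cost_per_cycle", "gamma", se_frac=0.10))
    for shared in (
        "palliative_drug_cost_per_cycle",
        "state_cost_base_per_cycle",
        "state_cost_per_haq_per_cycle",
        "nonmedical_cost_per_cycle",
        "indirect_cost_per_cycle",
    ):
        params.append(PSAParameter(f"arms.*.{shared}", "gamma", se_frac=0.10))
    params.append(PSAParameter("arms.*.utility.intercept", "beta", se=0.03))
    params.append(PSAParameter("arms.*.utility.slope", "beta", se=0.03))
    for cat in ("ACR20", "ACR50", "ACR70"):
        params.append(PSAParameter(f"arms.*.delta_haq.{cat}", "beta", se_frac=0.10, scale=3.0))
    return params


def sample_psa_config(
    config: ModelConfig,
    seed_or_rng,
    parameters: Optional[Sequence[PSAParameter]] = None,
) -> ModelConfig:
    """Draw one perturbed configuration for the PSA, deterministically.

    Scalar parameters are sampled from gamma/beta distributions centred on
    their base values; each arm's four-category response split is drawn from
    a Dirichlet with concentration equal to its observed category counts.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    if parameters is None:
        parameters = default_psa_parameters()
    draw = copy.deepcopy(config)
    for p in parameters:
        # one random draw per logical parameter: a shared (`arms.*`) input is
        # perturbed identically in both strategies
        paths = _expand(config, p.path)
        mean = get_parameter(config, paths[0])
        se = _se_of(p, mean)
        if se == 0:
            continue  # degenerate distribution: the draw equals the base
        if p.dist == "gamma":
            val = mean if mean <= 0 else _draw_gamma(mean, se, rng)
        elif p.dist == "beta":
            val = _draw_beta(mean / p.scale, se / p.scale, rng) * p.scale
        else:
            raise ConfigurationError(f"{p.path}: unknown distribution {p.dist!r}")
        rel = val / mean if mean else 0.0
        for path in paths:
            base = get_parameter(config, path)
            set_parameter(draw, path, val if base == mean else base * rel)
    for arm_name, arm in draw.arms.items():
        counts = arm.response_counts
        if counts is None:
            continue
        alpha = np.array([counts[c] for c in ("ACR70", "ACR50", "ACR20", "NONE")],
                         dtype=float)
        if np.any(alpha <= 0):
            raise ConfigurationError(f"arm {arm_name}: response counts must be > 0")
        probs = rng.dirichlet(alpha)
        arm.response = dict(zip(("ACR70", "ACR50", "ACR20", "NONE"), map(float, probs)))
    return draw


@dataclass
class PSAResult:
    draws: pd.DataFrame  # columns: iteration, delta_cost, delta_qalys
    n_iterations: int
    seed: int
    wtp_grid: np.ndarray
    ceac: np.ndarray
    wtp: float
    p_ce_at_wtp: float

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "probability": self.ceac})


def run_psa(
    config: ModelConfig,
    n_iterations: int = 5000,
    seed: int = 0,
    parameters: Optional[Sequence[PSAParameter]] = None,
    wtp_grid: Optional[np.ndarray] = None,
) -> PSAResult:
    """Monte Carlo PSA: per-iteration (ΔC, ΔQ) plus the CEAC.

    The WTP grid spans 0 to 5× per-capita GDP (the configured threshold is
    3× per-capita GDP) in 101 points; the headline probability is evaluated
    at the configured threshold.  All CEAC points use the same draw set.
    """
    if n_iterations < 1:
        raise ConfigurationError("n_iterations must be >= 1")
    config.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iterations):
        draw = sample_psa_config(config, rng, parameters)
        res = {a: summarize_trace(run_cohort(draw, a)) for a in draw.arms}
        inc = icer(res["tof"], res["ada"])
        rows.append((it, inc.delta_cost, inc.delta_qalys))
    draws = pd.DataFrame(rows, columns=["iteration", "delta_cost", "delta_qalys"])
    if wtp_grid is None:
        gdp = config.wtp_per_qaly / 3.0
        wtp_grid = np.linspace(0.0, 5.0 * gdp, 101)
    dc = draws["delta_cost"].to_numpy()
    dq = draws["delta_qalys"].to_numpy()
    ceac = np.array([(w * dq - dc > 0).mean() for w in wtp_grid])
    p_ce = float((config.wtp_per_qaly * dq - dc > 0).mean())
    return PSAResult(
        draws=draws,
        n_iterations=n_iterations,
        seed=seed,
        wtp_grid=np.asarray(wtp_grid, dtype=float),
        ceac=ceac,
        wtp=config.wtp_per_qaly,
        p_ce_at_wtp=p_ce,
    )
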