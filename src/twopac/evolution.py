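"""Agent-based birth-death model of the evolution of senescence.

Each haploid, asexual individual carries two evolvable life-history traits:
``x_b``, the age at which fertility ends, and ``x_d``, the age at which the
mortality risk becomes non-zero.  While younger than ``x_b`` an individual
gives birth; once older than ``x_d`` it dies at rate ``i_d``.  Newborns
copy the parent, each trait independently perturbed with probability
``p_mut`` by a centred Gaussian of standard deviation ``sigma_mut``,
truncated at zero (traits are ages).

Finite resources bound the population in one of two ways (``regulation``):

``"fecundity"`` (default)
    the birth rate is ``i_b * max(0, 1 - N/K)`` while fertile: crowding
    suppresses reproduction, and the mortality risk truly is zero before
    ``x_d``;
``"mortality"``
    the birth rate is ``i_b`` while fertile and every individual suffers
    an extra death rate ``c * N`` (classical logistic competition).

The fecundity form is the default because it preserves the defining
feature of the trait pair — no death before the senescence onset — and
with it the trait dynamics the model is meant to exhibit: both traits
creep upward indefinitely while their difference ``x_b - x_d`` settles at
a small positive value set by the intensities, high-fecundity populations
evolve shorter fertile periods, and fast-turnover populations explore
trait space faster.  Under mortality-side competition the crowding death
rate dwarfs the trait-dependent rates (at equilibrium ``c N`` is of the
order of ``i_b``), selection on both traits is exponentially suppressed
beyond the short competitive lifespan, and the trait pair performs a
nearly neutral random walk instead.

Nothing couples fertility and longevity directly; any relation between the
evolved ``x_b`` and ``x_d`` (in particular a stable positive gap
``x_b - x_d``, i.e. senescence setting in before fertility ends, and the
apparent longevity-fertility trade-off across ``i_b`` levels) is an
emergent property of the dynamics.

Two simulators are provided: an exact event-driven scheduler (rates are
piecewise constant between events and age-threshold crossings, so the
next-event time is re-sampled at the earliest crossing, which is valid by
memorylessness) and a fast fixed-step scheme whose per-step event
probabilities are the exact ``1 - exp(-rate * dt)``; the step is chosen
adaptively so no individual rate ever exceeds a few percent per step.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EvoIndividual",
    "EvoConfig",
    "TraitTrajectory",
    "run_bd_evolution",
    "trait_gap_summary",
    "exploration_speed",
]


@dataclass(frozen=True)
class EvoIndividual:
    """One individual: trait pair (days) and birth time (days)."""

    x_b: float
    x_d: float
    birth_time: float

    def __post_init__(self) -> None:
        if self.x_b < 0 or self.x_d < 0:
            raise ValueError("traits are ages and must be non-negative")


@dataclass(frozen=True)
class EvoConfig:
    """Configuration of the birth-death evolution run.

    Defaults give the standard study condition: fertility and senescence
    intensities of 2/day, competition tuned for an equilibrium population
    near 500 individuals, a 10% per-trait mutation probability with 0.5-day
    mutation steps, and founders with both traits at 2 days.
    """

    i_b: float = 2.0          # birth rate per day while fertile
    i_d: float = 2.0          # death hazard per day once senescent
    regulation: str = "fecundity"  # "fecundity" (K) or "mortality" (c N)
    K: float = 667.0          # carrying capacity (fecundity regulation)
    c: float = 0.004          # competition per day per individual (mortality regulation)
    p_mut: float = 0.1        # mutation probability per trait per birth
    sigma_mut: float = 0.5    # mutation SD, days
    n0: int = 500             # founder count
    x_b0: float = 2.0         # founder end-of-fertility age, days
    x_d0: float = 2.0         # founder senescence-onset age, days
    t_max: float = 200.0      # simulated time span, days
    record_every: float = 1.0 # trajectory sampling interval, days
    seed: int = 0
    hard_cap: int = 1_000_000 # abort threshold for runaway populations

    def __post_init__(self) -> None:
        if min(self.i_b, self.i_d, self.c, self.sigma_mut,
               self.x_b0, self.x_d0) < 0:
            raise ValueError("rates, mutation SD and founder traits must be >= 0")
        if self.regulation not in ("fecundity", "mortality"):
            raise ValueError("regulation must be 'fecundity' or 'mortality'")
        if self.K <= 0:
            raise ValueError("carrying capacity K must be positive")
        if not 0.0 <= self.p_mut <= 1.0:
            raise ValueError("p_mut must lie in [0, 1]")
        if self.n0 < 1:
            raise ValueError("need at least one founder")
        if self.t_max <= 0 or self.record_every <= 0:
            raise ValueError("t_max and record_every must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EvoConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "EvoConfig":
        """Load a configuration from a JSON or YAML file."""
        text = open(path, "r", encoding="utf-8").read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("evolution config file must hold a mapping")
        return cls.from_dict(data)


@dataclass
class TraitTrajectory:
    """Recorded time series of trait means and population bookkeeping.

    ``mean_*`` entries are NaN after extinction.  ``births`` and ``deaths``
    are cumulative counts, so ``n0 + births - deaths == pop_size`` at every
    recorded time.
    """

    times: np.ndarray
    mean_xb: np.ndarray
    mean_xd: np.ndarray
    mean_gap: np.ndarray
    pop_size: np.ndarray
    births: np.ndarray
    deaths: np.ndarray
    extinct: bool = False
    final_population: pd.DataFrame | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "mean_xb": self.mean_xb,
                "mean_xd": self.mean_xd,
                "mean_gap": self.mean_gap,
                "pop_size": self.pop_size,
                "births": self.births,
                "deaths": self.deaths,
            }
        )


def _mutate(values: np.ndarray, rng: np.random.Generator,
            p_mut: float, sigma: float) -> np.ndarray:
    out = values.copy()
    if p_mut > 0.0 and sigma > 0.0 and len(out):
        hit = rng.random(len(out)) < p_mut
        n_hit = int(hit.sum())
        if n_hit:
            out[hit] += rng.normal(0.0, sigma, n_hit)
            np.maximum(out, 0.0, out=out)
    return out


def run_bd_evolution(config: EvoConfig, method: str = "fixed-step",
                     dt: float | None = None) -> TraitTrajectory:
    """Run the birth-death evolution model.

    Parameters
    ----------
    config
        Model configuration; the run is deterministic given ``config.seed``.
    method
        ``"fixed-step"`` (default, fast) or ``"exact"`` (event-driven
        reference scheduler, for validation and small populations).
    dt
        Step for the fixed-step scheme.  By default the step adapts each
        iteration to ``0.05 / max per-individual rate`` (capped at
        ``record_every``), keeping per-step event probabilities below ~5%.

    Returns
    -------
    TraitTrajectory
        Trajectory sampled every ``record_every`` days, with the final
        population snapshot attached.  Extinction before ``t_max`` returns
        the truncated trajectory with ``extinct=True``; exceeding
        ``config.hard_cap`` individuals raises ``RuntimeError``.
    """
    if method == "fixed-step":
        return _run_fixed_step(config, dt)
    if method == "exact":
        return _run_exact(config)
    raise ValueError("method must be 'fixed-step' or 'exact'")


def _snapshot(xb, xd, bt) -> pd.DataFrame:
    return pd.DataFrame({"x_b": xb, "x_d": xd, "birth_time": bt})


def _record(rec, t, xb, xd, n_births, n_deaths):
    n = len(xb)
    rec["times"].append(t)
    rec["pop_size"].append(n)
    rec["births"].append(n_births)
    rec["deaths"].append(n_deaths)
    if n:
        mb, md = float(xb.mean()), float(xd.mean())
        rec["mean_xb"].append(mb)
        rec["mean_xd"].append(md)
        rec["mean_gap"].append(float((xb - xd).mean()))
    else:
        rec["mean_xb"].append(np.nan)
        rec["mean_xd"].append(np.nan)
        rec["mean_gap"].append(np.nan)


def _build(rec, extinct, xb, xd, bt) -> TraitTrajectory:
    return TraitTrajectory(
        times=np.asarray(rec["times"], dtype=float),
        mean_xb=np.asarray(rec["mean_xb"], dtype=float),
        mean_xd=np.asarray(rec["mean_xd"], dtype=float),
        mean_gap=np.asarray(rec["mean_gap"], dtype=float),
        pop_size=np.asarray(rec["pop_size"], dtype=np.int64),
        births=np.asarray(rec["births"], dtype=np.int64),
        deaths=np.asarray(rec["deaths"], dtype=np.int64),
        extinct=extinct,
        final_population=_snapshot(xb, xd, bt),
    )


def _per_capita_birth_rate(config: EvoConfig, n: int) -> float:
    if config.regulation == "fecundity":
        return config.i_b * max(0.0, 1.0 - n / config.K)
    return config.i_b


def _competition_death_rate(config: EvoConfig, n: int) -> float:
    return config.c * n if config.regulation == "mortality" else 0.0


def _run_fixed_step(config: EvoConfig, dt: float | None) -> TraitTrajectory:
    rng = np.random.default_rng(config.seed)
    xb = np.full(config.n0, float(config.x_b0))
    xd = np.full(config.n0, float(config.x_d0))
    bt = np.zeros(config.n0)
    t = 0.0
    n_births = 0
    n_deaths = 0
    rec = {k: [] for k in ("times", "mean_xb", "mean_xd", "mean_gap",
                           "pop_size", "births", "deaths")}
    _record(rec, t, xb, xd, n_births, n_deaths)
    next_record = config.record_every
    extinct = False
    while t < config.t_max - 1e-12:
        n = len(xb)
        if n == 0:
            extinct = True
            break
        birth_rate = _per_capita_birth_rate(config, n)
        comp = _competition_death_rate(config, n)
        if dt is None:
            r_max = birth_rate + config.i_d + comp
            step = min(0.05 / max(r_max, 1e-12), config.record_every)
        else:
            step = dt
        step = min(step, config.t_max - t, next_record - t)
        age = t - bt
        death_rate = config.i_d * (age > xd) + comp
        die = rng.random(n) < -np.expm1(-death_rate * step)
        p_birth = -np.expm1(-birth_rate * step)
        give = (age < xb) & (rng.random(n) < p_birth)
        parents = np.nonzero(give)[0]
        child_xb = _mutate(xb[parents], rng, config.p_mut, config.sigma_mut)
        child_xd = _mutate(xd[parents], rng, config.p_mut, config.sigma_mut)
        t += step
        keep = ~die
        n_deaths += int(die.sum())
        n_births += len(parents)
        xb = np.concatenate([xb[keep], child_xb])
        xd = np.concatenate([xd[keep], child_xd])
        bt = np.concatenate([bt[keep], np.full(len(parents), t)])
        if len(xb) > config.hard_cap:
            raise RuntimeError(
                f"population exceeded hard cap {config.hard_cap} at t={t:.2f}; "
                "the configuration is divergent"
            )
        if t >= next_record - 1e-9:
            _record(rec, t, xb, xd, n_births, n_deaths)
            next_record += config.record_every
    if extinct:
        _record(rec, t, xb, xd, n_births, n_deaths)
    return _build(rec, extinct, xb, xd, bt)


def _run_exact(config: EvoConfig) -> TraitTrajectory:
    """Event-driven reference scheduler (exact, O(N) per event)."""
    rng = np.random.default_rng(config.seed)
    xb = np.full(config.n0, float(config.x_b0))
    xd = np.full(config.n0, float(config.x_d0))
    bt = np.zeros(config.n0)
    t = 0.0
    n_births = 0
    n_deaths = 0
    rec = {k: [] for k in ("times", "mean_xb", "mean_xd", "mean_gap",
                           "pop_size", "births", "deaths")}
    _record(rec, t, xb, xd, n_births, n_deaths)
    next_record = config.record_every
    extinct = False
    while t < config.t_max - 1e-12:
        n = len(xb)
        if n == 0:
            extinct = True
            break
        age = t - bt
        birth_rates = _per_capita_birth_rate(config, n) * (age < xb)
        death_rates = config.i_d * (age > xd) + _competition_death_rate(config, n)
        total = float(birth_rates.sum() + death_rates.sum())
        # earliest deterministic change of any rate: an age crossing x_b or x_d
        crossings = []
        fert = age < xb
        pre = age < xd
        if fert.any():
            crossings.append(float((bt[fert] + xb[fert]).min()))
        if pre.any():
            crossings.append(float((bt[pre] + xd[pre]).min()))
        t_change = min(crossings) if crossings else np.inf
        # strictly advance past simultaneous crossings (e.g. identical founders)
        t_change = min(max(t_change, t + 1e-12), next_record, config.t_max)
        dt_event = rng.exponential(1.0 / total) if total > 0 else np.inf
        if t + dt_event >= t_change:
            t = t_change  # rates change; re-sample (memoryless)
            if t >= next_record - 1e-12:
                _record(rec, t, xb, xd, n_births, n_deaths)
                next_record += config.record_every
            continue
        t += dt_event
        rates = np.concatenate([birth_rates, death_rates])
        idx = int(rng.choice(2 * n, p=rates / rates.sum()))
        if idx < n:  # birth
            child_b = _mutate(xb[idx:idx + 1], rng, config.p_mut, config.sigma_mut)
            child_d = _mutate(xd[idx:idx + 1], rng, config.p_mut, config.sigma_mut)
            xb = np.concatenate([xb, child_b])
            xd = np.concatenate([xd, child_d])
            bt = np.concatenate([bt, [t]])
            n_births += 1
        else:  # death
            j = idx - n
            xb = np.delete(xb, j)
            xd = np.delete(xd, j)
            bt = np.delete(bt, j)
            n_deaths += 1
        if len(xb) > config.hard_cap:
            raise RuntimeError(
                f"population exceeded hard cap {config.hard_cap} at t={t:.2f}"
            )
    if extinct:
        _record(rec, t, xb, xd, n_births, n_deaths)
    return _build(rec, extinct, xb, xd, bt)


def trait_gap_summary(traj: TraitTrajectory, window: float = 0.25) -> float:
    """Time-averaged mean trait gap ``x_b - x_d`` over the trailing window.

    ``window`` is the trailing fraction of the recorded run to average
    over; a positive value means the onset of senescence precedes the end
    of fertility.  NaN entries (post-extinction) are ignored.
    """
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    if not 0.0 < window <= 1.0:
        raise ValueError("window must lie in (0, 1]")
    t = traj.times
    cut = t[-1] - window * (t[-1] - t[0])
    sel = t >= cut
    vals = traj.mean_gap[sel]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no finite trait records in the requested window")
    return float(vals.mean())


def exploration_speed(traj: TraitTrajectory, window: float) -> float:
    """Mean absolute drift speed of ``mean_xb``, in days per day.

    The recorded trajectory is cut into non-overlapping windows of length
    ``window`` days; within each, the speed is the absolute net change of
    ``mean_xb`` divided by the elapsed time, and the speeds are averaged.
    Faster genotypic exploration (larger values) is expected in
    configurations with quicker generational turnover.
    """
    t = traj.times
    x = traj.mean_xb
    ok = np.isfinite(x)
    t, x = t[ok], x[ok]
    if len(t) < 2:
        raise ValueError("need at least two finite trajectory points")
    speeds = []
    start = t[0]
    while start < t[-1] - 1e-12:
        end = min(start + window, t[-1])
        sel = (t >= start - 1e-12) & (t <= end + 1e-12)
        ts, xs = t[sel], x[sel]
        if len(ts) >= 2 and ts[-1] > ts[0]:
            speeds.append(abs(xs[-1] - xs[0]) / (ts[-1] - ts[0]))
        start = start + window
    if not speeds:
        raise ValueError("need at least two recorded points per window")
    return float(np.mean(speeds))
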