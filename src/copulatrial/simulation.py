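"""Scenario truths, correlated-outcome generation, the adaptive trial engine
and Monte-Carlo operating characteristics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import (
    DesignCriteria,
    DoseDecision,
    acceptable_doses,
    desirability_values,
    next_dose,
)
from .inference import (
    MCMCConfig,
    PriorSpec,
    TrialData,
    posterior_dose_summaries,
    sample_posterior,
)
from .model_core import (
    CopulaSpec,
    DoseGrid,
    MarginalPair,
    invert_braun_marginals,
    joint_table,
)

__all__ = [
    "ScenarioTruth",
    "TrialRecord",
    "OperatingCharacteristics",
    "load_scenarios",
    "get_scenario",
    "generate_outcomes",
    "run_trial",
    "operating_characteristics",
    "correlation_study",
    "sweep_experiment",
]

_CELL_OUTCOMES = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int64)


@dataclass(frozen=True)
class ScenarioTruth:
    """One row block of the scenario fixture: true per-dose marginals.

    ``d_values`` and ``optimal_dose`` are derived from the pairs with the
    default design criteria; a scenario where no dose is truly acceptable
    has ``optimal_dose`` of ``None`` (the correct decision is futility).
    """

    scenario: int
    pairs: Tuple[MarginalPair, ...]
    d_values: Tuple[float, ...]
    optimal_dose: Optional[int]
    grid: DoseGrid = DoseGrid()

    def pair(self, dose: int) -> MarginalPair:
        return self.pairs[self.grid.levels.index(dose)]


def load_scenarios(criteria: DesignCriteria = DesignCriteria()) -> Dict[int, ScenarioTruth]:
    """Read the shipped scenario table and derive desirability/optimal dose."""
    with resources.files("copulatrial.data").joinpath("scenarios.csv").open() as fh:
        df = pd.read_csv(fh)
    out: Dict[int, ScenarioTruth] = {}
    for sid, sub in df.groupby("scenario"):
        sub = sub.sort_values("dose")
        grid = DoseGrid(tuple(int(z) for z in sub["dose"]))
        pairs = tuple(MarginalPair(float(t), float(e)) for t, e in zip(sub["pi_T"], sub["pi_E"]))
        d_vals = tuple(
            float(d) for d in desirability_values(sub["pi_T"].to_numpy(), sub["pi_E"].to_numpy(), criteria)
        )
        acceptable = [
            z
            for z, p in zip(grid.levels, pairs)
            if p.pi_T < criteria.pibar_T and p.pi_E > criteria.piunder_E
        ]
        optimal = None
        if acceptable:
            optimal = max(acceptable, key=lambda z: d_vals[grid.levels.index(z)])
        out[int(sid)] = ScenarioTruth(int(sid), pairs, d_vals, optimal, grid)
    return out


def get_scenario(scenario: int, criteria: DesignCriteria = DesignCriteria()) -> ScenarioTruth:
    scenarios = load_scenarios(criteria)
    if scenario not in scenarios:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {sorted(scenarios)}")
    return scenarios[scenario]


def _generating_table(pair: MarginalPair, copula: CopulaSpec, braun_truth_mode: str):
    """Joint table whose realized marginals honor the scenario truth.

    For the Braun family in ``invert`` mode the scenario marginals are first
    mapped back to copula parameters so the generated data match the stated
    truth at any association level; ``raw`` mode plugs the scenario values in
    as copula parameters directly.
    """
    if copula.family == "braun" and braun_truth_mode == "invert":
        pair = invert_braun_marginals(pair, copula.psi)
    elif braun_truth_mode not in ("invert", "raw"):
        raise ValueError("braun_truth_mode must be 'invert' or 'raw'")
    return joint_table(pair, copula)


def generate_outcomes(
    scenario: ScenarioTruth,
    dose: int,
    copula: CopulaSpec,
    n: int,
    rng: np.random.Generator,
    braun_truth_mode: str = "invert",
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` correlated binary (toxicity, efficacy) pairs at one dose."""
    if n < 1:
        raise ValueError("n must be >= 1")
    table = _generating_table(scenario.pair(dose), copula, braun_truth_mode)
    cells = rng.choice(4, size=n, p=table.as_array())
    outcomes = _CELL_OUTCOMES[cells]
    return outcomes[:, 0].copy(), outcomes[:, 1].copy()


@dataclass(frozen=True)
class CohortLog:
    cohort: int
    dose: int
    acceptable_set: Tuple[int, ...]
    desirability: Dict[int, float]


@dataclass(frozen=True)
class TrialRecord:
    """Full record of one simulated adaptive trial."""

    data: TrialData
    cohorts: Tuple[CohortLog, ...]
    status: str  # "futility" or "completed"
    selected_dose: Optional[int]
    subjects_per_dose: Tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.status not in ("futility", "completed"):
            raise ValueError(f"unknown status {self.status!r}")
        if sum(self.subjects_per_dose) != len(self.data):
            raise ValueError("subjects-per-dose tally does not match accrued data")


def run_trial(
    scenario: ScenarioTruth,
    gen_copula: CopulaSpec,
    fit_family: str,
    prior: PriorSpec = PriorSpec(),
    criteria: DesignCriteria = DesignCriteria(),
    mcmc: MCMCConfig = MCMCConfig(),
    seed: int = 0,
    cohort_size: int = 3,
    max_cohorts: int = 15,
    braun_truth_mode: str = "invert",
) -> TrialRecord:
    """Simulate one adaptive trial under the five-step dose-finding rule.

    The first cohort is treated at the lowest dose unconditionally.  After
    every cohort the posterior is refit on all accrued data, the acceptable
    set is screened and the next dose chosen (no skipping while escalating);
    the trial stops early for futility when no dose is acceptable, otherwise
    the most desirable acceptable dose is selected at full accrual.
    """
    grid = scenario.grid
    ss = np.random.SeedSequence(seed)
    gen_seeds, fit_seeds = ss.spawn(2)
    gen_rngs = [np.random.Generator(np.random.PCG64(s)) for s in gen_seeds.spawn(max_cohorts)]
    fit_ints = fit_seeds.generate_state(max_cohorts)

    data = TrialData.empty()
    cohorts: List[CohortLog] = []
    current_dose = grid.levels[0]
    highest_tried = grid.levels[0]
    per_dose = {z: 0 for z in grid.levels}
    status, selected = "completed", None

    for c in range(max_cohorts):
        y_t, y_e = generate_outcomes(
            scenario, current_dose, gen_copula, cohort_size, gen_rngs[c], braun_truth_mode
        )
        data = data.extend([current_dose] * cohort_size, y_t, y_e)
        per_dose[current_dose] += cohort_size
        highest_tried = max(highest_tried, current_dose)

        with warnings.catch_warnings():
            # arms not yet visited are expected mid-trial
            warnings.simplefilter("ignore", UserWarning)
            draws = sample_posterior(data, fit_family, prior, mcmc, seed=int(fit_ints[c]), grid=grid)
        pi_t, pi_e = posterior_dose_summaries(draws, grid)
        acceptable = acceptable_doses(pi_t, pi_e, criteria, grid)
        d_by_dose = dict(
            zip(grid.levels, desirability_values(pi_t.mean(axis=0), pi_e.mean(axis=0), criteria))
        )
        cohorts.append(CohortLog(c + 1, current_dose, acceptable, d_by_dose))

        last = c == max_cohorts - 1
        decision = next_dose(highest_tried, acceptable, d_by_dose, at_max_sample_size=last)
        if decision.action == "stop_futility":
            status = "futility"
            break
        if decision.action == "select":
            selected = decision.dose
            break
        current_dose = decision.dose

    return TrialRecord(
        data=data,
        cohorts=tuple(cohorts),
        status=status,
        selected_dose=selected,
        subjects_per_dose=tuple(per_dose[z] for z in grid.levels),
        seed=seed,
    )


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo summaries of the design over replicated trials."""

    scenario: int
    gen_family: str
    gen_psi: Optional[float]
    fit_family: str
    n_trials: int
    selection_prop: Tuple[float, ...]
    futility_prop: float
    mean_subjects: Tuple[float, ...]
    grid: DoseGrid = DoseGrid()

    def __post_init__(self) -> None:
        total = self.futility_prop + sum(self.selection_prop)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("selection and futility proportions must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                scenario=self.scenario,
                gen_family=self.gen_family,
                gen_psi=self.gen_psi,
                fit_family=self.fit_family,
                n_trials=self.n_trials,
                dose="futility",
                selection_prop=self.futility_prop,
                mean_subjects=0.0,
            )
        ]
        for z, sel, sub in zip(self.grid.levels, self.selection_prop, self.mean_subjects):
            rows.append(
                dict(
                    scenario=self.scenario,
                    gen_family=self.gen_family,
                    gen_psi=self.gen_psi,
                    fit_family=self.fit_family,
                    n_trials=self.n_trials,
                    dose=str(z),
                    selection_prop=sel,
                    mean_subjects=sub,
                )
            )
        return pd.DataFrame(rows)


def operating_characteristics(
    scenario: ScenarioTruth,
    gen_copula: CopulaSpec,
    fit_family: str,
    n_trials: int,
    base_seed: int = 0,
    prior: PriorSpec = PriorSpec(),
    criteria: DesignCriteria = DesignCriteria(),
    mcmc: MCMCConfig = MCMCConfig(),
    cohort_size: int = 3,
    max_cohorts: int = 15,
    braun_truth_mode: str = "invert",
    n_jobs: int = 1,
    return_records: bool = False,
):
    """Aggregate :func:`run_trial` over independent replicate seeds."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    seeds = [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(base_seed).spawn(n_trials)]

    def one(s: int) -> TrialRecord:
        return run_trial(
            scenario, gen_copula, fit_family, prior, criteria, mcmc, s, cohort_size, max_cohorts, braun_truth_mode
        )

    if n_jobs != 1:
        from joblib import Parallel, delayed

        records = Parallel(n_jobs=n_jobs)(delayed(one)(s) for s in seeds)
    else:
        records = [one(s) for s in seeds]

    grid = scenario.grid
    sel = np.zeros(grid.k)
    fut = 0
    subj = np.zeros(grid.k)
    for r in records:
        if r.status == "futility":
            fut += 1
        else:
            sel[grid.levels.index(r.selected_dose)] += 1
        subj += np.asarray(r.subjects_per_dose, dtype=float)
    oc = OperatingCharacteristics(
        scenario=scenario.scenario,
        gen_family=gen_copula.family,
        gen_psi=gen_copula.psi,
        fit_family=fit_family,
        n_trials=n_trials,
        selection_prop=tuple(sel / n_trials),
        futility_prop=fut / n_trials,
        mean_subjects=tuple(subj / n_trials),
        grid=grid,
    )
    if return_records:
        return oc, records
    return oc


def correlation_study(
    scenario: ScenarioTruth,
    copula: CopulaSpec,
    n_reps: int,
    base_seed: int = 0,
    n_per_dose: int = 11,
    prior: PriorSpec = PriorSpec(),
    mcmc: MCMCConfig = MCMCConfig(),
    braun_truth_mode: str = "invert",
) -> Dict[str, object]:
    """Estimability of the association parameter in a fixed design.

    Each replicate treats ``n_per_dose`` subjects at every dose, fits the
    *matching* copula family and records the posterior mean of psi; the
    mean and standard deviation of those posterior means are reported.
    """
    if copula.family == "independence":
        raise ValueError("the independence model has no association parameter")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    grid = scenario.grid
    post_means = np.empty(n_reps)
    for i, ss in enumerate(np.random.SeedSequence(base_seed).spawn(n_reps)):
        gen_ss, fit_ss = ss.spawn(2)
        rng = np.random.Generator(np.random.PCG64(gen_ss))
        data = TrialData.empty()
        for z in grid.levels:
            y_t, y_e = generate_outcomes(scenario, z, copula, n_per_dose, rng, braun_truth_mode)
            data = data.extend([z] * n_per_dose, y_t, y_e)
        draws = sample_posterior(
            data, copula.family, prior, mcmc, seed=int(fit_ss.generate_state(1)[0]), grid=grid
        )
        post_means[i] = float(draws.column("psi").mean())
    return {
        "family": copula.family,
        "psi": copula.psi,
        "scenario": scenario.scenario,
        "n_reps": n_reps,
        "n_per_dose": n_per_dose,
        "mean": float(post_means.mean()),
        "sd": float(post_means.std(ddof=1)) if n_reps > 1 else float("nan"),
        "posterior_means": post_means,
    }


def sweep_experiment(
    axis: str,
    values: Sequence,
    scenario: ScenarioTruth,
    gen_copula: CopulaSpec,
    fit_family: str,
    n_trials: int,
    base_seed: int = 0,
    cohort_size: int = 3,
    **kwargs,
) -> pd.DataFrame:
    """Repeat the operating-characteristics run varying one named axis.

    ``axis`` is ``"max_sample_size"`` (e.g. 30/45/60/75 subjects, converted
    to a cohort count) or ``"prior_set"`` (named presets).  Returns a tidy
    long-format table with one row per condition and dose.
    """
    if axis not in ("max_sample_size", "prior_set"):
        raise ValueError("axis must be 'max_sample_size' or 'prior_set'")
    frames = []
    for v in values:
        if axis == "max_sample_size":
            n = int(v)
            if n % cohort_size:
                raise ValueError(f"max sample size {n} is not a multiple of cohort size {cohort_size}")
            oc = operating_characteristics(
                scenario,
                gen_copula,
                fit_family,
                n_trials,
                base_seed,
                cohort_size=cohort_size,
                max_cohorts=n // cohort_size,
                **kwargs,
            )
        else:
            oc = operating_characteristics(
                scenario,
                gen_copula,
                fit_family,
                n_trials,
                base_seed,
                prior=PriorSpec.preset(str(v)),
                cohort_size=cohort_size,
                **kwargs,
            )
        frame = oc.to_frame()
        frame.insert(0, axis, v)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
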