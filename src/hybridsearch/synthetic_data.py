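"""Seeded generators for hybrid-search, change-detection, and go/no-go tables.

The hybrid-search generator emulates the online experiment's design: 110
participants x 112 trials, memory and visual set sizes crossed over
{1, 2, 4, 8}, scene context on half the trials, target present on half, a
7 s response deadline, and a fixed stimulus (image) assigned to each design
slot so that every participant answers the same stimuli in a unique random
order.  Responses and RTs are drawn from the condition-mapped drift-diffusion
model; participant heterogeneity enters as a Gaussian shift on non-decision
time, calibrated so the random-intercept share of RT variance (ICC) matches
the target value.

The change-detection generator draws each participant's true capacity K and
produces responses from the whole-display guessing model that Cowan's formula
inverts; the go/no-go generator draws per-participant sensitivity and
criterion and produces responses from the equal-variance signal-detection
model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .hybrid_ddm import HybridDDMSpec, map_condition, DESIGN_LEVELS
from .ddm_core import _simulate_arrays
from .trial_io import TrialTable

__all__ = [
    "CdtConfig",
    "GngConfig",
    "GeneratorConfig",
    "generate_experiment",
    "generate_cdt",
    "generate_gng",
    "calibrate_participant_sd",
    "write_manifest",
]

# participant t0 spread (seconds) calibrated by bisection so the fitted
# random-intercept ICC of RT ~ VSS * Context lands on 0.15
DEFAULT_PARTICIPANT_SD = 0.53


@dataclass(frozen=True)
class CdtConfig:
    """Change-detection task: 120 trials, set sizes 4 and 6 (60 each)."""

    n_trials: int = 120
    set_sizes: tuple = (4, 6)
    change_probability: float = 0.5
    k_mean: float = 2.31
    k_sd: float = 0.82
    guess_rate: float = 0.1


@dataclass(frozen=True)
class GngConfig:
    """Go/no-go task: 150 trials at a 4:1 go/no-go ratio."""

    n_trials: int = 150
    go_fraction: float = 0.8
    d_prime_mean: float = 2.5
    d_prime_sd: float = 0.5
    c_mean: float = -0.23
    c_sd: float = 0.58


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters for the synthetic experiment."""

    n_participants: int = 110
    n_trials: int = 112
    spec: HybridDDMSpec = field(default_factory=HybridDDMSpec)
    participant_sd: float = DEFAULT_PARTICIPANT_SD
    min_t0: float = 0.05  # floor on shifted non-decision time
    dt: float = 0.005
    stimulus_outliers: tuple = ()  # ((stimulus_id, shift_seconds), ...)
    cdt: CdtConfig = field(default_factory=CdtConfig)
    gng: GngConfig = field(default_factory=GngConfig)
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:16]


def _design_table(n_trials: int) -> pd.DataFrame:
    """Fixed stimulus/design assignment shared by all participants.

    Each of the 16 {MSS, VSS} pairs receives n_trials/16 slots; the four
    {context, target} combinations are balanced within pair up to +-1, and
    the combination left short rotates across pairs so each appears on
    exactly half the trials overall.
    """
    pairs = [(m, v) for m in DESIGN_LEVELS for v in DESIGN_LEVELS]
    per_pair, extra = divmod(n_trials, len(pairs))
    combos = [(False, False), (False, True), (True, False), (True, True)]
    rows = []
    for i, (mss, vss) in enumerate(pairs):
        n_here = per_pair + (1 if i < extra else 0)
        # rotate the combo order per pair so shortfalls spread evenly
        order = combos[i % 4:] + combos[: i % 4]
        for j in range(n_here):
            ctx, tp = order[j % 4]
            rows.append({"mss": mss, "vss": vss, "context_present": ctx, "target_present": tp})
    df = pd.DataFrame(rows)
    df["stimulus_id"] = [f"stim{i:03d}" for i in range(len(df))]
    return df


def generate_experiment(config: GeneratorConfig | None = None, seed: int | None = None) -> TrialTable:
    """Simulate the full hybrid-search experiment as a validated TrialTable.

    Every trial's (response, rt) is drawn from the DDM mapped to its design
    cell with the participant's non-decision-time shift; timeouts at 7 s
    become response "none".  Reproducible under a fixed seed.
    """
    config = config or GeneratorConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    design = _design_table(config.n_trials)
    n_p, n_t = config.n_participants, len(design)

    t0_shift = rng.normal(0.0, config.participant_sd, size=n_p)

    # per-trial DDM parameters for participant-independent pieces
    base = [
        map_condition(config.spec, int(r.mss), int(r.vss), bool(r.context_present), bool(r.target_present))
        for r in design.itertuples(index=False)
    ]
    mu_trial = np.array([p.mu for p in base])
    b_trial = np.array([p.boundary for p in base])
    t0_trial = np.array([p.t0 for p in base])

    frames = []
    for i in range(n_p):
        pid = f"P{i:03d}"
        order = rng.permutation(n_t)
        t0_i = np.maximum(t0_trial[order] + t0_shift[i], config.min_t0)
        upper, rt = _simulate_arrays(
            mu_trial[order],
            b_trial[order],
            t0_i,
            sigma=config.spec.sigma,
            contaminant_lambda=config.spec.contaminant_lambda,
            t_max=config.spec.t_max,
            n=n_t,
            dt=config.dt,
            rng=rng,
        )
        df = design.iloc[order].reset_index(drop=True).copy()
        df.insert(0, "participant_id", pid)
        df.insert(1, "trial_index", np.arange(n_t))
        responded = np.isfinite(rt)
        response = np.where(responded, np.where(upper == 1.0, "present", "absent"), "none")
        df["response"] = response
        df["rt"] = rt
        correct = np.where(
            responded,
            (response == "present") == df["target_present"].to_numpy(),
            np.nan,
        )
        df["correct"] = correct
        frames.append(df)

    data = pd.concat(frames, ignore_index=True)

    for stim_id, shift in config.stimulus_outliers:
        mask = (data["stimulus_id"] == stim_id) & (data["response"] != "none")
        data.loc[mask, "rt"] = np.clip(
            data.loc[mask, "rt"] + shift, None, config.spec.t_max - 0.01
        )

    data = data[
        [
            "participant_id",
            "trial_index",
            "stimulus_id",
            "mss",
            "vss",
            "context_present",
            "target_present",
            "response",
            "rt",
            "correct",
        ]
    ]
    table = TrialTable.from_dataframe(data, validate=False)
    table.provenance.append(
        {
            "rule": "generate_experiment",
            "seed": seed,
            "config_hash": config.config_hash(),
            "rows": len(data),
        }
    )
    return table


def generate_cdt(config: GeneratorConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Simulate the change-detection task.

    Each participant's true capacity K is drawn from a normal (truncated at
    0); on each trial the probed item is in memory with probability
    min(1, K/N).  A change is detected when the item is in memory; otherwise
    the participant guesses "change" at the configured guess rate.  This is
    exactly the generative model inverted by K = N (H - FA).
    """
    config = config or GeneratorConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cdt = config.cdt
    per_size = cdt.n_trials // len(cdt.set_sizes)
    rows = []
    for i in range(config.n_participants):
        pid = f"P{i:03d}"
        k_true = max(0.0, rng.normal(cdt.k_mean, cdt.k_sd))
        for n_items in cdt.set_sizes:
            d = min(1.0, k_true / n_items)
            change = rng.random(per_size) < cdt.change_probability
            in_memory = rng.random(per_size) < d
            guess = rng.random(per_size) < cdt.guess_rate
            # detected change -> "change"; undetected -> guess
            resp_change = np.where(change, in_memory | (~in_memory & guess), ~in_memory & guess)
            for c, r in zip(change, resp_change):
                rows.append(
                    {
                        "participant_id": pid,
                        "set_size": n_items,
                        "change_present": bool(c),
                        "response_change": bool(r),
                        "k_true": k_true,
                    }
                )
    return pd.DataFrame(rows)


def generate_gng(config: GeneratorConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Simulate the go/no-go task under the equal-variance SDT model.

    Per participant, sensitivity d' and criterion c are drawn from normals;
    go trials elicit a response with probability Phi(d'/2 - c) and no-go
    trials with probability Phi(-d'/2 - c).
    """
    config = config or GeneratorConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    gng = config.gng
    n_go = round(gng.n_trials * gng.go_fraction)
    n_nogo = gng.n_trials - n_go
    rows = []
    for i in range(config.n_participants):
        pid = f"P{i:03d}"
        d_true = rng.normal(gng.d_prime_mean, gng.d_prime_sd)
        c_true = rng.normal(gng.c_mean, gng.c_sd)
        p_hit = norm.cdf(d_true / 2.0 - c_true)
        p_fa = norm.cdf(-d_true / 2.0 - c_true)
        is_go = np.concatenate([np.ones(n_go, bool), np.zeros(n_nogo, bool)])
        rng.shuffle(is_go)
        p = np.where(is_go, p_hit, p_fa)
        responded = rng.random(gng.n_trials) < p
        for g, r in zip(is_go, responded):
            rows.append(
                {
                    "participant_id": pid,
                    "is_go": bool(g),
                    "responded": bool(r),
                    "d_prime_true": d_true,
                    "c_true": c_true,
                }
            )
    return pd.DataFrame(rows)


def calibrate_participant_sd(
    config: GeneratorConfig | None = None,
    target_icc: float = 0.15,
    lo: float = 0.0,
    hi: float = 1.0,
    tol: float = 0.01,
    max_iter: int = 10,
    seed: int = 0,
) -> float:
    """Tune the participant t0 spread so the fitted ICC hits ``target_icc``.

    Bisection on ``participant_sd``: each probe generates an experiment,
    filters it for RT analysis, fits the trial-level random-intercept model
    RT ~ VSS * Context on target-present trials, and reads off the ICC.
    """
    from .trial_io import filter_for_rt_analysis
    from .setsize_stats import fit_random_intercept_lmm

    config = config or GeneratorConfig()

    def icc_at(sd: float) -> float:
        table = generate_experiment(replace(config, participant_sd=sd), seed=seed)
        kept = filter_for_rt_analysis(table)
        df = kept.data[kept.data["target_present"]]
        res = fit_random_intercept_lmm(df, set_size="vss")
        return res.icc

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        icc = icc_at(mid)
        if abs(icc - target_icc) < tol:
            return mid
        if icc < target_icc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def write_manifest(path, config: GeneratorConfig, seed: int, extra: dict | None = None) -> None:
    """JSON manifest tying generated CSVs to their seed and configuration."""
    payload = {"seed": seed, "config_hash": config.config_hash(), "config": asdict(config)}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
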