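"""Synthetic screening campaigns: truth, picks, replicates, kinetic traces.

Every pipeline stage can be exercised without any external data.  A campaign
is generated in layers, each a pure function of its parameters and a seed:

1. per-member *true* secretion activities (``gen_true_activities``) — either
   resampled from the packaged activity-table multiset ("fixture" mode,
   range ~0–13.1 U/mL as in the study) or lognormal (defaults mu=1.08,
   sigma=1.05, fitted once to the log of the positive fixture means);
2. clone picks drawn through the same categorical sampler as the screening
   simulator, so a generated campaign's multiplicity spectrum is exactly a
   ``simulate_picks`` draw;
3. replicate activities with multiplicative Gaussian noise,
   ``a * (1 + N(0, cv))`` truncated at zero — matching the roughly
   proportional replicate SDs of the study (default cv 0.15);
4. kinetic traces whose slope is the exact algebraic inverse of the assay
   reduction, plus additive Gaussian absorbance noise.

Because layer 4 inverts :func:`secscreen.assay.activity_from_slope` exactly,
the end-to-end identity holds: at zero noise, generated traces reduce to the
stated activity to machine precision and true ranks are reproduced perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assay import AssayConfig, KineticTrace
from .occupancy import LibraryDesign
from .simulate import _campaign_rng, _draw_members

__all__ = [
    "CampaignTruth",
    "gen_true_activities",
    "gen_campaign",
    "gen_traces",
    "campaign_recovery_rate",
    "LOGNORMAL_MU",
    "LOGNORMAL_SIGMA",
]

#: Lognormal truth parameters, fitted once to ln(positive fixture means).
LOGNORMAL_MU = 1.08
LOGNORMAL_SIGMA = 1.05

#: Default coefficient of variation of biological replicates.
DEFAULT_REPLICATE_CV = 0.15


@dataclass(frozen=True)
class CampaignTruth:
    """Ground truth of a synthetic campaign (the oracle for recovery tests)."""

    library: LibraryDesign
    true_activity_per_sp: np.ndarray  # U/mL, one entry per library member
    replicate_cv: float
    seed: int

    def __post_init__(self) -> None:
        a = np.asarray(self.true_activity_per_sp, dtype=float)
        if a.shape != (self.library.n_members,):
            raise ValueError("need one true activity per library member")
        if np.any(a < 0):
            raise ValueError("true activities must be non-negative")
        if self.replicate_cv < 0:
            raise ValueError("replicate CV must be non-negative")
        object.__setattr__(self, "true_activity_per_sp", a)

    def sp_id(self, member: int) -> str:
        return f"SP{member + 1:03d}"


def gen_true_activities(
    N: int,
    mode: str = "fixture",
    params: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw per-member true activities (U/mL).

    "fixture" mode samples with replacement from the packaged activity-table
    multiset for *C. glutamicum* (so ties occur, as repeated isolates do in
    practice); "lognormal" mode draws from LogNormal(mu, sigma) with the
    fitted defaults, giving distinct values.
    """
    if int(N) != N or N < 1:
        raise ValueError(f"library size must be a positive integer, got {N}")
    params = dict(params or {})
    rng = np.random.default_rng([int(seed), 0x7A07])
    if mode == "fixture":
        from .io import HOST_CG, load_campaign_table  # deferred: io imports phenotype

        frame = load_campaign_table().frame
        pool = frame.loc[frame["host"] == HOST_CG, "activity_U_per_mL"].to_numpy()
        return rng.choice(pool, size=N, replace=True)
    if mode == "lognormal":
        mu = float(params.get("mu", LOGNORMAL_MU))
        sigma = float(params.get("sigma", LOGNORMAL_SIGMA))
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        return rng.lognormal(mu, sigma, size=N)
    raise ValueError(f"unknown truth mode {mode!r}; expected 'fixture' or 'lognormal'")


def gen_campaign(
    truth: CampaignTruth,
    n_clones: int,
    n_replicates: int,
    *,
    host: str = "synthetic",
) -> pd.DataFrame:
    """Pick clones and measure noisy replicate activities.

    Returns a long table in the phenotyping input schema (clone_id, sp_id,
    host, replicate, activity, units) plus a ``member`` column tying each
    clone back to the truth.  Picks reuse the simulator's sampler and seed
    policy (replicate stream 0 of ``truth.seed``); replicate noise draws from
    stream 1, so picks are unchanged if only the noise model is revisited.
    """
    if int(n_clones) != n_clones or n_clones < 0:
        raise ValueError("n_clones must be a non-negative integer")
    if int(n_replicates) != n_replicates or n_replicates < 1:
        raise ValueError("n_replicates must be a positive integer")
    pick_rng = _campaign_rng(truth.seed, 0)
    members = _draw_members(pick_rng, n_clones, truth.library.weights)
    noise_rng = _campaign_rng(truth.seed, 1)
    rows = []
    for clone_idx, member in enumerate(members):
        a_true = truth.true_activity_per_sp[member]
        noisy = a_true * (1.0 + noise_rng.normal(0.0, truth.replicate_cv, size=n_replicates))
        noisy = np.maximum(noisy, 0.0)  # assay floors at zero
        for rep, value in enumerate(noisy, start=1):
            rows.append(
                {
                    "clone_id": f"clone{clone_idx + 1:04d}",
                    "sp_id": truth.sp_id(int(member)),
                    "member": int(member),
                    "host": host,
                    "replicate": rep,
                    "activity": float(value),
                    "units": "U/mL",
                }
            )
    return pd.DataFrame(
        rows, columns=["clone_id", "sp_id", "member", "host", "replicate", "activity", "units"]
    )


def activity_to_slope(activity: float, cfg: AssayConfig, dilution_factor: float) -> float:
    """Exact inverse of the assay conversion: well slope (1/min) for an activity."""
    return (
        activity
        * cfg.epsilon_cm2_per_umol
        * cfg.path_length_cm
        * (cfg.sample_volume_uL / cfg.reaction_volume_uL)
        / dilution_factor
    )


def gen_traces(
    activity: float,
    cfg: AssayConfig,
    dilution_factor: float = 1.0,
    duration_s: float = 600.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    interval_s: float = 25.0,
    a0: float = 0.05,
    blank_rate_per_min: float = 0.0,
    well_id: str = "synth",
) -> tuple[KineticTrace, KineticTrace]:
    """Generate a (sample, blank) trace pair for a stated true activity.

    The sample trace carries the activity-derived slope *plus* the blank
    drift, so the standard reduce-and-blank pipeline recovers ``activity``
    exactly at ``noise_sd=0``.  Readings are every ``interval_s`` seconds
    (25 s nominal) over ``duration_s``.
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    if activity < 0:
        raise ValueError("activity must be non-negative")
    if duration_s < 3 * interval_s:
        raise ValueError("trace must span at least 3 sampling intervals")
    times = np.arange(0.0, duration_s + 1e-9, interval_s)
    rng = np.random.default_rng([int(seed), 0x7ACE])
    slope_min = activity_to_slope(activity, cfg, dilution_factor)
    sample_abs = a0 + (slope_min + blank_rate_per_min) / 60.0 * times
    blank_abs = a0 + blank_rate_per_min / 60.0 * times
    if noise_sd > 0:
        sample_abs = sample_abs + rng.normal(0.0, noise_sd, size=times.shape)
        blank_abs = blank_abs + rng.normal(0.0, noise_sd, size=times.shape)
    sample = KineticTrace(
        well_id=well_id, role="sample", times_s=times, absorbances=sample_abs,
        dilution_factor=dilution_factor,
    )
    blank = KineticTrace(
        well_id=f"{well_id}_blank", role="blank", times_s=times, absorbances=blank_abs,
    )
    return sample, blank


def campaign_recovery_rate(
    n_campaigns: int = 200,
    n_clones: int = 66,
    n_replicates: int = 8,
    cv: float = 0.1,
    N: int = 148,
    mode: str = "lognormal",
    seed: int = 0,
) -> float:
    """Fraction of campaigns whose top-ranked SP is truly the best picked SP.

    Each campaign draws a fresh truth, picks ``n_clones`` clones, measures
    ``n_replicates`` noisy replicates, aggregates per SP and ranks; success
    means the top-ranked SP's true activity equals the maximum true activity
    among the picked clones (exact true ties count as success, since either
    answer is correct).  Lognormal truths are the default here because the
    fixture multiset contains exact ties that would make "the best SP"
    ill-defined as an oracle.
    """
    from .phenotype import SPRecord, rank_sps

    if n_campaigns < 1:
        raise ValueError("need at least one campaign")
    library = LibraryDesign(N)
    successes = 0
    for c in range(n_campaigns):
        campaign_seed = (int(seed) * 100_003 + c) % (2**31)
        truth = CampaignTruth(
            library=library,
            true_activity_per_sp=gen_true_activities(N, mode=mode, seed=campaign_seed),
            replicate_cv=cv,
            seed=campaign_seed,
        )
        table = gen_campaign(truth, n_clones, n_replicates)
        records = [
            SPRecord.from_replicates(sp, "synthetic", grp["activity"].tolist())
            for sp, grp in table.groupby("sp_id")
        ]
        top = rank_sps(records)[0]
        picked_members = table["member"].unique()
        best_true = truth.true_activity_per_sp[picked_members].max()
        top_member = int(top.sp_id.removeprefix("SP")) - 1
        if truth.true_activity_per_sp[top_member] == best_true:
            successes += 1
    return successes / n_campaigns
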