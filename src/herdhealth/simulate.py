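"""Synthetic multi-herd Holstein population with known genetic parameters.

Generates, from one seeded configuration: a sire--MGS pedigree with skewed
sire usage; true breeding values consistent with a target genetic covariance
``G_true`` over the pedigree; per-herd fixed effects; lactation histories
with abortion flags, disposal and end-of-study censoring; a dated raw
treatment-event log (with deliberate window duplicates and same-day repeats
for the cleaning rules to remove); correlated 305-d production/SCS
phenotypes; and 1-9 conformation scores.  Ground truth is retained so every
downstream stage -- event cleaning, costing, relationship matrices, REML --
can be tested for parameter recovery without any external data.

Health events arise from a liability-threshold mechanism: a cow's liability
for a category is ``lambda * (standardized THC breeding value) + N(0, 1)``,
thresholded so that the realized fraction of first lactations with at least
one treated case matches the configured incidence target.  Affected
lactations draw a zero-truncated Poisson number of illness episodes.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import PedigreeTable
from .treatments import CATEGORIES, TREATMENT_TYPES, DedupKind

# Herd sizes (first-parity cows) used by default: eight herds totalling 2,214.
DEFAULT_HERD_SIZES = [394, 227, 427, 402, 179, 152, 250, 183]

DEFAULT_INCIDENCE = {
    "MAST": 0.265,
    "REPRO": 0.133,
    "LAME": 0.267,
    "META": 0.077,
    "MISC": 0.141,
}

# mean illness episodes per affected lactation (zero-truncated Poisson)
DEFAULT_EPISODE_MEANS = {
    "MAST": 1.3,
    "REPRO": 1.2,
    "LAME": 1.5,
    "META": 1.1,
    "MISC": 1.2,
}

# which specific treatment an episode in a category is recorded as
DEFAULT_CODE_PROBS = {
    "MAST": {"mastitis": 0.78, "mastitis_test": 0.22},
    "REPRO": {"metritis": 0.60, "retained_placenta": 0.20, "cystic_ovary": 0.13, "misc_repro": 0.07},
    "LAME": {"hoof": 1.0},
    "META": {"digestive": 0.40, "displaced_abomasum": 0.19, "ketosis": 0.21, "milk_fever": 0.20},
    "MISC": {"other": 0.40, "respiratory": 0.35, "injury": 0.25},
}

# per-parity trait means (305-d production and SCS scale; THC on the
# Gaussian analysis scale used for parameter-recovery studies)
DEFAULT_TRAIT_MEANS = {
    "THC": [57.91, 73.92, 87.95],
    "milk": [10943.0, 12628.0, 13018.0],
    "fat": [395.0, 449.0, 464.0],
    "protein": [331.0, 389.0, 401.0],
    "SCS": [2.21, 2.33, 2.63],
}

DEFAULT_CONFORMATION_MEANS = {"stature": 5.6, "dairy_form": 5.4, "udder_depth": 6.7}


def build_covariances(
    traits: list[str],
    h2: dict[str, float],
    phen_sd: dict[str, float],
    genetic_corr: dict[tuple[str, str], float],
    phen_corr: dict[tuple[str, str], float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (G, R) from heritabilities, phenotypic SDs and correlations.

    Residual covariances are chosen so realized phenotypic correlations hit
    ``phen_corr`` (defaulting to 0 where unspecified).
    """
    t = len(traits)
    G = np.zeros((t, t))
    R = np.zeros((t, t))
    phen_corr = phen_corr or {}

    def _lookup(d, a, b, default=0.0):
        return d.get((a, b), d.get((b, a), default))

    for i, a in enumerate(traits):
        vp = phen_sd[a] ** 2
        G[i, i] = h2[a] * vp
        R[i, i] = (1.0 - h2[a]) * vp
        for j, b in enumerate(traits[:i]):
            g12 = _lookup(genetic_corr, a, b) * np.sqrt(G[i, i] * h2[b] * phen_sd[b] ** 2)
            p12 = _lookup(phen_corr, a, b) * phen_sd[a] * phen_sd[b]
            G[i, j] = G[j, i] = g12
            R[i, j] = R[j, i] = p12 - g12
    for name, M in (("G", G), ("R", R)):
        w = np.linalg.eigvalsh(M)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError(f"{name} implied by the requested correlations is not PSD")
    return G, R


def default_covariances(traits: list[str] | None = None) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Default three-trait structure: THC, 305-d milk and SCS.

    First-parity heritabilities 0.25 / 0.23 / 0.18; genetic correlations
    THC-milk 0.44, THC-SCS 0.93, milk-SCS 0.13; phenotypic correlations
    THC-milk -0.07 and THC-SCS 0.14.
    """
    traits = traits or ["THC", "milk", "SCS"]
    h2 = {"THC": 0.25, "milk": 0.23, "fat": 0.20, "protein": 0.20, "SCS": 0.18}
    phen_sd = {"THC": 100.0, "milk": 1300.0, "fat": 45.0, "protein": 38.0, "SCS": 1.8}
    g_corr = {("THC", "milk"): 0.44, ("THC", "SCS"): 0.93, ("milk", "SCS"): 0.13}
    p_corr = {("THC", "milk"): -0.07, ("THC", "SCS"): 0.14}
    G, R = build_covariances(traits, h2, phen_sd, g_corr, p_corr)
    return traits, G, R


@dataclass
class SimulationConfig:
    """All knobs of the synthetic herd; defaults emulate the 8-herd study."""

    herd_sizes: list[int] = field(default_factory=lambda: list(DEFAULT_HERD_SIZES))
    n_sires: int = 260
    n_mgs: int = 420
    trait_list: list[str] = field(default_factory=lambda: ["THC", "milk", "SCS"])
    G_true: np.ndarray | None = None
    R_true: np.ndarray | None = None
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    herd_effect_sd: dict = field(
        default_factory=lambda: {"THC": 15.0, "milk": 500.0, "fat": 18.0, "protein": 15.0, "SCS": 0.35}
    )
    incidence_targets: dict = field(default_factory=lambda: dict(DEFAULT_INCIDENCE))
    episode_means: dict = field(default_factory=lambda: dict(DEFAULT_EPISODE_MEANS))
    code_probs: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CODE_PROBS.items()})
    liability_slope: float = 0.5
    calving_window: tuple = (dt.date(2008, 3, 1), dt.date(2015, 10, 31))
    study_end: dt.date = dt.date(2015, 11, 30)
    lactation_length_mean: float = 332.0
    lactation_length_sd: float = 45.0
    dry_period_days: float = 60.0
    survival: tuple = (0.85, 0.73)  # P(parity 2 | 1), P(parity 3 | 2)
    censor_fraction: float = 0.06  # disposed (sold/died) mid-lactation
    abortion_fraction: float = 0.045
    duplicate_prob: float = 0.25
    sameday_prob: float = 0.10
    dry_period_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.G_true is None or self.R_true is None:
            traits, G, R = default_covariances(self.trait_list)
            self.trait_list = traits
            self.G_true = G if self.G_true is None else np.asarray(self.G_true, dtype=float)
            self.R_true = R if self.R_true is None else np.asarray(self.R_true, dtype=float)
        self.G_true = np.atleast_2d(np.asarray(self.G_true, dtype=float))
        self.R_true = np.atleast_2d(np.asarray(self.R_true, dtype=float))
        t = len(self.trait_list)
        for name, M in (("G_true", self.G_true), ("R_true", self.R_true)):
            if M.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t} to match trait_list")
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(M).min() < -1e-8 * max(abs(M).max(), 1.0):
                raise ValueError(f"{name} must be positive semidefinite")
        if self.n_sires < 1 or any(h < 1 for h in self.herd_sizes):
            raise ValueError("herd sizes and sire count must be positive")
        if sum(self.herd_sizes) < self.n_sires:
            raise ValueError("need at least as many cows as sires")
        for c, p in self.incidence_targets.items():
            if not 0.0 <= p < 1.0:
                raise ValueError(f"incidence target for {c} must be in [0, 1)")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ValueError("censor_fraction must be in [0, 1)")

    @property
    def n_herds(self) -> int:
        return len(self.herd_sizes)

    @property
    def n_cows(self) -> int:
        return int(sum(self.herd_sizes))


@dataclass
class TrueValues:
    """Ground truth retained for recovery tests."""

    breeding_values: pd.DataFrame  # animal_id x trait
    herd_effects: pd.DataFrame  # herd_id x trait
    liabilities: pd.DataFrame | None = None  # cow-lactation category liabilities


@dataclass
class SimulatedHerd:
    config: SimulationConfig
    pedigree: PedigreeTable
    cows: pd.DataFrame  # cow_id, herd_id, sire_id, mgs_id
    lactations: pd.DataFrame
    events: pd.DataFrame
    phenotypes_305d: pd.DataFrame
    conformation: pd.DataFrame
    truth: TrueValues

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.pedigree.to_frame().to_csv(out / "pedigree.csv", index=False)
        self.cows.to_csv(out / "cows.csv", index=False)
        self.lactations.to_csv(out / "lactations.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        self.phenotypes_305d.to_csv(out / "305d.csv", index=False)
        self.conformation.to_csv(out / "conformation.csv", index=False)
        self.truth.breeding_values.to_csv(out / "truth_breeding_values.csv")
        self.truth.herd_effects.to_csv(out / "truth_herd_effects.csv")


def simulate_pedigree(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[PedigreeTable, pd.DataFrame]:
    """Cows assigned to herds, sired by a skewed-usage AI-bull pool.

    Sire usage follows Dirichlet weights (a few heavily used bulls, a long
    tail of lightly used ones) so the two-descendant edit has real work to
    do; MGS are drawn from a separate, likewise skewed pool.  Sires and MGS
    are founders with unknown parents.
    """
    n = config.n_cows
    sire_ids = [f"S{i + 1:04d}" for i in range(config.n_sires)]
    mgs_ids = [f"M{i + 1:04d}" for i in range(config.n_mgs)]
    sire_w = rng.dirichlet(np.full(config.n_sires, 0.35)) if config.n_sires > 1 else np.array([1.0])
    mgs_w = rng.dirichlet(np.full(config.n_mgs, 0.5)) if config.n_mgs > 1 else np.array([1.0])

    cow_ids = [f"C{i + 1:05d}" for i in range(n)]
    herd = np.repeat([f"H{j + 1}" for j in range(config.n_herds)], config.herd_sizes)
    sire = rng.choice(sire_ids, size=n, p=sire_w)
    mgs = rng.choice(mgs_ids, size=n, p=mgs_w)
    cows = pd.DataFrame(
        {"cow_id": cow_ids, "herd_id": herd, "sire_id": sire, "mgs_id": mgs}
    )
    ped_frame = pd.concat(
        [
            pd.DataFrame({"animal_id": sire_ids, "sire_id": "", "mgs_id": ""}),
            pd.DataFrame({"animal_id": mgs_ids, "sire_id": "", "mgs_id": ""}),
            cows[["cow_id", "sire_id", "mgs_id"]].rename(columns={"cow_id": "animal_id"}),
        ],
        ignore_index=True,
    )
    return PedigreeTable.from_frame(ped_frame), cows


def simulate_breeding_values(
    pedigree: PedigreeTable,
    G_true: np.ndarray,
    rng: np.random.Generator,
    trait_list: list[str] | None = None,
) -> pd.DataFrame:
    """Breeding values down the pedigree: u = 1/2 u_sire + 1/4 u_mgs + phi.

    Founders draw N(0, G); the Mendelian residual phi has covariance
    d * G with d from the sire-MGS recursion (11/16 for a non-inbred known
    sire/MGS pair, more when a parent is unknown).
    """
    G = np.atleast_2d(np.asarray(G_true, dtype=float))
    t = G.shape[0]
    trait_list = trait_list or [f"trait{i + 1}" for i in range(t)]
    w, V = np.linalg.eigh(G)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))  # G = L L'
    d = pedigree.mendelian_variances()
    n = len(pedigree)
    z = rng.standard_normal((n, t))
    u = np.zeros((n, t))
    for i in range(n):
        s, m = pedigree.sire[i], pedigree.mgs[i]
        val = np.sqrt(d[i]) * (L @ z[i])
        if s >= 0:
            val = val + 0.5 * u[s]
        if m >= 0:
            val = val + 0.25 * u[m]
        u[i] = val
    return pd.DataFrame(u, index=pd.Index(pedigree.ids, name="animal_id"), columns=trait_list)


def _zt_rate_for_mean(mean: float) -> float:
    """Poisson rate whose zero-truncated mean equals ``mean`` (> 1)."""
    if mean <= 1.0:
        return 0.0
    from scipy.optimize import brentq

    return float(brentq(lambda lam: lam / (1.0 - np.exp(-lam)) - mean, 1e-9, 50.0))


def _zt_poisson(rate: float, rng: np.random.Generator) -> int:
    """Zero-truncated Poisson draw by inversion of the conditional CDF."""
    if rate <= 0:
        return 1
    u = rng.random()
    p0 = np.exp(-rate)
    target = p0 + u * (1.0 - p0)  # CDF value conditioned on k >= 1
    k, cdf, pk = 0, p0, p0
    while cdf < target and k < 1000:
        k += 1
        pk *= rate / k
        cdf += pk
    return max(k, 1)


def simulate_lactations(
    config: SimulationConfig, cows: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Calving histories with censoring, disposal and abortion flags."""
    start, stop = config.calving_window
    window_days = (stop - start).days
    end_day = (config.study_end - start).days
    rows = []
    for cow, herd in zip(cows["cow_id"], cows["herd_id"]):
        calving = float(rng.integers(0, window_days + 1))
        for parity in (1, 2, 3):
            length = float(
                np.clip(
                    rng.normal(config.lactation_length_mean, config.lactation_length_sd),
                    200.0,
                    500.0,
                )
            )
            end = calving + length
            reason = "completed"
            aborted = bool(rng.random() < config.abortion_fraction)
            if rng.random() < config.censor_fraction:
                end = calving + float(rng.uniform(15.0, max(length - 1.0, 16.0)))
                reason = "sold" if rng.random() < 0.7 else "died"
            if end > end_day:
                end = float(end_day)
                reason = "in_progress"
            rows.append(
                {
                    "cow_id": cow,
                    "herd_id": herd,
                    "parity": parity,
                    "calving_date": _date(start, calving),
                    "end_date": _date(start, end),
                    "end_reason": reason,
                    "abortion": aborted,
                }
            )
            if reason != "completed":
                break
            if rng.random() >= config.survival[parity - 1 if parity <= 2 else 1]:
                break
            calving = end + float(rng.normal(config.dry_period_days, 10.0))
            if parity >= 3 or calving > end_day:
                break
    return pd.DataFrame(rows)


def _date(start: dt.date, offset_days: float) -> dt.date:
    return start + dt.timedelta(days=int(round(offset_days)))


def simulate_events(
    truth: TrueValues,
    config: SimulationConfig,
    lactations: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Raw (uncleaned) dated treatment log, with decoy duplicates.

    Liability per category: lambda * standardized THC breeding value plus a
    standard-normal environmental draw, thresholded to hit the incidence
    target.  Each affected lactation draws a zero-truncated Poisson number
    of episodes, each recorded as a specific treatment.  Deliberate
    within-window duplicates, same-day repeats and sparse dry-period records
    are added so the deduplication and aggregation rules are exercised.
    """
    lam = config.liability_slope
    bv = truth.breeding_values
    if "THC" in bv.columns:
        g_sd = float(np.sqrt(max(config.G_true[config.trait_list.index("THC"), config.trait_list.index("THC")], 1e-300)))
        u_std = bv["THC"] / g_sd if g_sd > 0 else bv["THC"] * 0.0
    else:
        u_std = pd.Series(0.0, index=bv.index)
    liab_sd = np.sqrt(1.0 + lam * lam)

    thresholds = {
        c: stats.norm.ppf(1.0 - p, scale=liab_sd) if p > 0 else np.inf
        for c, p in config.incidence_targets.items()
    }
    ep_rates = {
        c: _zt_rate_for_mean(config.episode_means.get(c, 1.0)) for c in CATEGORIES
    }
    records = []
    for row in lactations.itertuples(index=False):
        cow = row.cow_id
        calving = pd.Timestamp(row.calving_date)
        end = pd.Timestamp(row.end_date)
        span = max((end - calving).days, 1)
        u = float(u_std.get(cow, 0.0))
        for cat in CATEGORIES:
            p = config.incidence_targets.get(cat, 0.0)
            liab = lam * u + rng.standard_normal()
            if p <= 0.0 or liab <= thresholds[cat]:
                continue
            n_ep = _zt_poisson(ep_rates[cat], rng)
            probs = config.code_probs[cat]
            codes = rng.choice(list(probs), size=n_ep, p=list(probs.values()))
            for code in codes:
                day = int(rng.integers(0, span + 1))
                date = calving + pd.Timedelta(days=day)
                records.append((cow, date, code))
                t = TREATMENT_TYPES[code]
                if rng.random() < config.sameday_prob:
                    records.append((cow, date, code))  # same-day repeat
                if rng.random() < config.duplicate_prob:
                    if t.dedup is DedupKind.WINDOW:
                        off = int(rng.integers(1, t.window_days))
                    elif t.dedup is DedupKind.ONCE_PER_LACTATION:
                        off = int(rng.integers(5, 30))
                    else:
                        off = 0
                    if off:
                        records.append((cow, date + pd.Timedelta(days=off), code))
        # sparse events in the dry period after this lactation (they must
        # aggregate to this parity, not the next)
        if row.end_reason == "completed" and rng.random() < config.dry_period_rate:
            code = rng.choice(["hoof", "mastitis", "injury"])
            day = int(rng.integers(1, int(config.dry_period_days)))
            records.append((cow, end + pd.Timedelta(days=day), code))

    ev = pd.DataFrame(records, columns=["cow_id", "date", "treatment_code"])
    if not ev.empty:
        ev = ev.sort_values(["cow_id", "date", "treatment_code"], kind="stable").reset_index(drop=True)
    return ev


def simulate_phenotypes(
    truth: TrueValues,
    config: SimulationConfig,
    lactations: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """305-d production/SCS table and first-parity conformation scores.

    Each cow-parity row is  mean(trait, parity) + herd effect + breeding
    value + residual,  residuals drawn jointly from ``R_true``.  The three
    conformation traits are discretized from latent normals to integer
    scores clamped to 1-9, scored once in first parity.
    """
    traits = config.trait_list
    t = len(traits)
    w, V = np.linalg.eigh(config.R_true)
    Lr = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    bv = truth.breeding_values
    he = truth.herd_effects

    lac = lactations
    rows = np.empty((len(lac), t))
    for i, row in enumerate(lac.itertuples(index=False)):
        parity = int(row.parity)
        means = np.array(
            [config.trait_means.get(tr, [0.0, 0.0, 0.0])[min(parity, 3) - 1] for tr in traits]
        )
        u = bv.loc[row.cow_id].to_numpy() if row.cow_id in bv.index else np.zeros(t)
        h = he.loc[row.herd_id].to_numpy() if row.herd_id in he.index else np.zeros(t)
        e = Lr @ rng.standard_normal(t)
        rows[i] = means + h + u + e
    phen = lac[["cow_id", "herd_id", "parity"]].copy()
    for j, tr in enumerate(traits):
        phen[tr] = rows[:, j]

    first = lac[lac["parity"] == 1][["cow_id", "herd_id"]].drop_duplicates("cow_id")
    conf = first.copy()
    for tr, mean in DEFAULT_CONFORMATION_MEANS.items():
        latent = rng.normal(mean, 1.5, size=len(conf))
        conf[tr] = np.clip(np.rint(latent), 1, 9).astype(int)
    return phen.reset_index(drop=True), conf.reset_index(drop=True)


def simulate_herd_effects(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    herds = [f"H{j + 1}" for j in range(config.n_herds)]
    eff = {
        tr: rng.normal(0.0, config.herd_effect_sd.get(tr, 0.0), size=len(herds))
        for tr in config.trait_list
    }
    return pd.DataFrame(eff, index=pd.Index(herds, name="herd_id"))


def simulate_herd(config: SimulationConfig) -> SimulatedHerd:
    """Run the whole generator under one seed."""
    rng = np.random.default_rng(config.seed)
    pedigree, cows = simulate_pedigree(config, rng)
    bv = simulate_breeding_values(pedigree, config.G_true, rng, config.trait_list)
    herd_effects = simulate_herd_effects(config, rng)
    truth = TrueValues(breeding_values=bv, herd_effects=herd_effects)
    lactations = simulate_lactations(config, cows, rng)
    events = simulate_events(truth, config, lactations, rng)
    phen, conf = simulate_phenotypes(truth, config, lactations, rng)
    return SimulatedHerd(
        config=config,
        pedigree=pedigree,
        cows=cows,
        lactations=lactations,
        events=events,
        phenotypes_305d=phen,
        conformation=conf,
        truth=truth,
    )
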