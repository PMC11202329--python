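"""Synthetic hospitalization-episode generator.

Emulates the hierarchical statistical structure of episode-level hospital
cost data: a few hundred base diagnostic groups with Zipf-like frequencies,
four severity levels with a geometrically decaying mix, gamma-distributed
complexity sub-indices (QIDP, QIDA, QIDC for diagnoses; QIPP, QIPS for
procedures) whose location grows with severity, and a lognormal episode
cost driven by base group, severity, procedures and demographics. Cheap
admissions vastly outnumber expensive ones; the default calibration puts
the mean near €4,935 and the median near €2,616.

The generator is the package's stand-in for confidential hospital accounting
data; everything downstream (groupers, evaluation, prediction) is exercised
against it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from casemix.config import GeneratorConfig
from casemix.errors import DataError

EPISODE_COLUMNS = [
    "episode_id",
    "age",
    "sex",
    "base_group",
    "severity",
    "qidp",
    "qida",
    "qidc",
    "qipp",
    "qips",
    "direct_cost",
    "indirect_cost",
    "total_cost",
]

# Gamma shapes and base scales (at severity 1) for the five sub-indices.
# Shapes < ~2 give the right-skewed, mass-near-zero profile of additive
# complexity scores; scales set the index-point magnitudes.
_INDEX_PARAMS = {
    "qidp": (2.0, 3.0),
    "qida": (1.5, 2.5),
    "qidc": (1.2, 1.5),
    "qipp": (2.0, 4.0),
    "qips": (1.3, 2.5),
}


def base_group_probabilities(config: GeneratorConfig) -> np.ndarray:
    """Zipf-like base-group frequencies: p_k ∝ k**(-zipf_exponent)."""
    ranks = np.arange(1, config.n_base_groups + 1, dtype=float)
    w = ranks ** (-config.zipf_exponent)
    return w / w.sum()


def severity_probabilities(config: GeneratorConfig) -> np.ndarray:
    """Geometric severity mix: lower severities dominate."""
    w = config.severity_decay ** np.arange(config.severity_levels, dtype=float)
    return w / w.sum()


def generate_population(
    config: GeneratorConfig, *, return_params: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Draw a full episode table from the generator.

    Parameters
    ----------
    config
        Generator parameters; validation happens on construction, so any
        `GeneratorConfig` instance is safe to pass.
    return_params
        If True, also return the latent truth used for the draw (base-group
        effects and mixture probabilities), which parameter-recovery tests
        compare fitted models against.

    Returns
    -------
    A DataFrame with one row per episode and the columns in
    ``EPISODE_COLUMNS``. Identical config (including seed) reproduces the
    table bit-identically.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_episodes

    # Latent per-group effects are drawn first, in a fixed order, so the
    # stream layout (and hence determinism) does not depend on n.
    base_effects = rng.normal(0.0, config.base_effect_sd, size=config.n_base_groups)
    p_base = base_group_probabilities(config)
    p_sev = severity_probabilities(config)

    base_idx = rng.choice(config.n_base_groups, size=n, p=p_base)
    severity = rng.choice(config.severity_levels, size=n, p=p_sev) + 1

    decades = np.array(sorted(config.age_weights), dtype=int)
    w_age = np.array([config.age_weights[d] for d in decades], dtype=float)
    decade = decades[rng.choice(len(decades), size=n, p=w_age / w_age.sum())]
    span = np.where(decade >= 100, 6, 10)  # open-ended 100+ band
    age = decade + rng.integers(0, span, size=n)

    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")

    # Sub-indices: gamma points whose scale grows with severity.
    sev_factor = 1.0 + config.severity_index_gradient * (severity - 1)
    indices = {}
    for name, (shape, scale) in _INDEX_PARAMS.items():
        indices[name] = np.round(rng.gamma(shape, scale * sev_factor, size=n), 0)

    qip = indices["qipp"] + indices["qips"]
    qip_sd = qip.std()
    qip_z = (qip - qip.mean()) / qip_sd if qip_sd > 0 else np.zeros(n)

    age_mult = np.array([config.age_multipliers[d] for d in decades])[
        np.searchsorted(decades, decade)
    ]
    sex_mult = np.where(sex == "male", config.sex_multipliers["male"], config.sex_multipliers["female"])

    log_cost = (
        config.global_log_mean
        + base_effects[base_idx]
        + config.severity_effect * (severity - 1)
        + config.procedure_effect * qip_z
        + np.log(age_mult * sex_mult)
        + rng.normal(0.0, config.noise_sd, size=n)
    )
    total = np.exp(log_cost)

    # Direct/indirect split: per-episode Beta jitter around the target share.
    f = config.indirect_fraction
    if 0 < f < 1:
        conc = config.indirect_jitter_concentration
        frac = rng.beta(f * conc, (1 - f) * conc, size=n)
    else:
        frac = np.full(n, f)
    indirect = total * frac
    direct = total - indirect

    width = max(7, len(str(n)))
    table = pd.DataFrame(
        {
            "episode_id": np.char.add("E", np.char.zfill(np.arange(1, n + 1).astype(str), width)),
            "age": age,
            "sex": sex,
            "base_group": np.char.add("G", np.char.zfill((base_idx + 1).astype(str), 3)),
            "severity": severity,
            "qidp": indices["qidp"],
            "qida": indices["qida"],
            "qidc": indices["qidc"],
            "qipp": indices["qipp"],
            "qips": indices["qips"],
            "direct_cost": direct,
            "indirect_cost": indirect,
            # summing the two parts keeps the additivity invariant exact
            "total_cost": direct + indirect,
        }
    )

    if return_params:
        params = {
            "base_effects": base_effects,
            "base_probabilities": p_base,
            "severity_probabilities": p_sev,
            "global_log_mean": config.global_log_mean,
            "severity_effect": config.severity_effect,
            "noise_sd": config.noise_sd,
        }
        return table, params
    return table


def age_band(age: pd.Series | np.ndarray) -> pd.Series:
    """Map age in years to the decade band label used in cost summaries."""
    age = pd.Series(np.asarray(age))
    decade = (age // 10 * 10).clip(upper=100).astype(int)
    labels = decade.astype(str) + "-" + (decade + 9).astype(str)
    return labels.mask(decade >= 100, "100+")


def summarize_costs(episodes: pd.DataFrame) -> pd.DataFrame:
    """Mean and median (IQR) total cost by sex and by age decade.

    Returns a tidy table with one row per sex level and one per age band:
    columns ``stratum_type`` ('sex' / 'age_group'), ``stratum``, ``n``,
    ``mean``, ``median``, ``q25``, ``q75``.
    """
    if len(episodes) == 0:
        raise DataError("summarize_costs: episode table is empty")

    def _stats(g: pd.Series) -> pd.Series:
        return pd.Series(
            {
                "n": g.size,
                "mean": g.mean(),
                "median": g.median(),
                "q25": g.quantile(0.25),
                "q75": g.quantile(0.75),
            }
        )

    parts = []
    by_sex = episodes.groupby("sex", observed=True)["total_cost"].apply(_stats).unstack()
    by_sex.insert(0, "stratum_type", "sex")
    parts.append(by_sex.rename_axis("stratum").reset_index())

    bands = age_band(episodes["age"])
    order = sorted(bands.unique(), key=lambda b: int(b.split("-")[0].rstrip("+")))
    by_age = (
        episodes["total_cost"]
        .groupby(pd.Categorical(bands, categories=order, ordered=True), observed=True)
        .apply(_stats)
        .unstack()
    )
    by_age.insert(0, "stratum_type", "age_group")
    parts.append(by_age.rename_axis("stratum").reset_index())

    out = pd.concat(parts, ignore_index=True)
    out["n"] = out["n"].astype(int)
    return out[["stratum_type", "stratum", "n", "mean", "median", "q25", "q75"]]


def write_episodes(episodes: pd.DataFrame, path: str | Path) -> None:
    """Write the episode table as CSV with the documented fixed header."""
    episodes.to_csv(path, index=False, columns=EPISODE_COLUMNS)


def read_episodes(path: str | Path) -> pd.DataFrame:
    """Read an episode CSV, validating the schema and core invariants."""
    table = pd.read_csv(path)
    missing = set(EPISODE_COLUMNS) - set(table.columns)
    if missing:
        raise DataError(f"episode file {path} is missing column(s): {sorted(missing)}")
    if len(table) == 0:
        raise DataError(f"episode file {path} contains no episodes")
    if table["episode_id"].duplicated().any():
        raise DataError(f"episode file {path} has duplicated episode_id values")
    if (table["total_cost"] <= 0).any():
        raise DataError(f"episode file {path} has non-positive total_cost values")
    return table
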