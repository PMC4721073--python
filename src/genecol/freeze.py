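"""Electrolyte-leakage freeze testing: index of injury and cold-hardiness summary.

After an artificial freeze test, cell damage is quantified by relative
electrolytic conductivity.  For a sample frozen at test temperature ``t``
with leachate conductance ``Lt`` (after freezing) and ``Lk`` (after heat
kill of the same sample), and an unfrozen control with conductances
``L0`` (control) and ``Ld`` (heat-killed control), the index of injury is

    It = 100 * (Rt - R0) / (1 - R0),   Rt = Lt / Lk,   R0 = L0 / Ld.

``It`` is 0 when the frozen sample leaks no more than the control and 100
when freezing released as many electrolytes as the heat kill.  Noisy
controls can push the raw index slightly outside [0, 100]; by default the
reported index is clamped to that range while the raw value is retained.

Cold hardiness is summarized per growth chamber from the two freeze
treatments whose mean injury is nearest 50% (maximum discrimination among
populations), as least-squares (adjusted) population means from an
additive population + freeze-treatment fixed-effects model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InjuryResult",
    "injury_index",
    "injury_table",
    "TemperatureSelection",
    "select_test_temperatures",
    "cold_hardiness_summary",
]


@dataclass(frozen=True)
class InjuryResult:
    """Index of injury for one freeze sample.

    Attributes
    ----------
    rt, r0 : float
        Relative conductances of the frozen sample and the unfrozen control.
    injury : float
        Index of injury (%), clamped to [0, 100] when requested.
    injury_raw : float
        Unclamped index; equals ``injury`` unless clamping was applied.
    """

    rt: float
    r0: float
    injury: float
    injury_raw: float


def _validate_conductances(lt, lk, l0, ld) -> None:
    lt, lk, l0, ld = (np.asarray(x, dtype=float) for x in (lt, lk, l0, ld))
    if np.any(lk <= 0):
        raise ValueError("heat-kill conductance Lk must be positive")
    if np.any(lt <= 0):
        raise ValueError("post-freeze conductance Lt must be positive")
    if np.any(lt > lk * (1 + 1e-12)):
        raise ValueError("Lt must not exceed the heat-kill conductance Lk")
    if np.any(l0 <= 0):
        raise ValueError("control conductance L0 must be positive")
    if np.any(ld <= l0):
        raise ValueError("degenerate control: heat-kill conductance Ld must exceed L0")


def injury_index(lt, lk, l0, ld, clamp: bool = True):
    """Index of injury from the four conductances.

    Accepts scalars or aligned arrays.  Returns an :class:`InjuryResult`
    for scalar input, else a dict of arrays with the same fields.

    Raises
    ------
    ValueError
        If any conductance violates 0 < Lt <= Lk or 0 < L0 < Ld.
    """
    _validate_conductances(lt, lk, l0, ld)
    lt, lk, l0, ld = (np.asarray(x, dtype=float) for x in (lt, lk, l0, ld))
    rt = lt / lk
    r0 = l0 / ld
    raw = 100.0 * (rt - r0) / (1.0 - r0)
    injury = np.clip(raw, 0.0, 100.0) if clamp else raw
    if injury.ndim == 0:
        return InjuryResult(float(rt), float(r0), float(injury), float(raw))
    return {"rt": rt, "r0": r0, "injury": injury, "injury_raw": raw}


def injury_table(
    samples: pd.DataFrame, controls: pd.DataFrame, clamp: bool = True
) -> pd.DataFrame:
    """Compute the index of injury for a table of freeze samples.

    Parameters
    ----------
    samples : DataFrame
        Columns ``sample_id, seedlot_id, chamber_id, batch_id,
        test_temperature, Lt, Lk``.
    controls : DataFrame
        Columns ``batch_id, L0, Ld`` — one control per measurement batch.
    clamp : bool
        Clamp the reported index to [0, 100] (raw value kept in
        ``injury_raw``).

    Returns
    -------
    DataFrame with the sample identifiers plus ``rt, r0, injury_raw, injury``.
    """
    missing = set(samples["batch_id"]) - set(controls["batch_id"])
    if missing:
        raise ValueError(f"no control for batches: {sorted(missing)}")
    merged = samples.merge(controls[["batch_id", "L0", "Ld"]], on="batch_id", how="left")
    res = injury_index(
        merged["Lt"].to_numpy(),
        merged["Lk"].to_numpy(),
        merged["L0"].to_numpy(),
        merged["Ld"].to_numpy(),
        clamp=clamp,
    )
    if isinstance(res, InjuryResult):  # single-row table
        res = {k: np.atleast_1d(v) for k, v in vars(res).items()}
    out = merged.drop(columns=["L0", "Ld"]).copy()
    out["rt"] = res["rt"]
    out["r0"] = res["r0"]
    out["injury_raw"] = res["injury_raw"]
    out["injury"] = res["injury"]
    return out


class TemperatureSelection(NamedTuple):
    pair: tuple[float, float]
    means: dict[float, float]


def select_test_temperatures(
    injury: pd.DataFrame,
    temperature: str = "test_temperature",
    population: str = "seedlot_id",
    value: str = "injury",
) -> TemperatureSelection:
    """Pick the two freeze temperatures with mean injury nearest 50%.

    The across-population mean (mean of per-population means, so each
    population counts once) is computed per test temperature; the two
    temperatures closest to 50% damage are returned, ties broken toward
    the colder temperature.  The pair is ordered warmest first.
    """
    temps = injury[temperature].unique()
    if len(temps) < 2:
        raise ValueError("need at least two distinct test temperatures")
    pop_means = injury.groupby([temperature, population], sort=True)[value].mean()
    means = pop_means.groupby(level=0).mean()
    # sort by |mean - 50| then colder (more negative) first on ties
    order = sorted(means.index, key=lambda t: (abs(means[t] - 50.0), t))
    chosen = sorted(order[:2], reverse=True)  # warmer first
    return TemperatureSelection(
        pair=(float(chosen[0]), float(chosen[1])),
        means={float(t): float(m) for t, m in means.items()},
    )


def _ls_means_one_chamber(df: pd.DataFrame, population: str, treatment: str, value: str) -> pd.Series:
    """LS means from an additive population + treatment fixed-effects model.

    Reference-coded OLS; the LS mean of a population is its prediction
    averaged over all treatment levels (equal weight per treatment).
    """
    pops = pd.Categorical(df[population])
    trts = pd.Categorical(df[treatment])
    n = len(df)
    p_codes = pops.codes
    t_codes = trts.codes
    n_pop = len(pops.categories)
    n_trt = len(trts.categories)
    X = np.zeros((n, 1 + (n_pop - 1) + (n_trt - 1)))
    X[:, 0] = 1.0
    for j in range(1, n_pop):
        X[p_codes == j, j] = 1.0
    for j in range(1, n_trt):
        X[t_codes == j, n_pop - 1 + j] = 1.0
    beta, *_ = np.linalg.lstsq(X, df[value].to_numpy(float), rcond=None)
    mu = beta[0]
    pop_eff = np.concatenate([[0.0], beta[1:n_pop]])
    trt_eff = np.concatenate([[0.0], beta[n_pop : n_pop + n_trt - 1]])
    ls = mu + pop_eff + trt_eff.mean()
    return pd.Series(ls, index=list(pops.categories))


def cold_hardiness_summary(
    injury: pd.DataFrame,
    selected: Sequence[float],
    population: str = "seedlot_id",
    chamber: str = "chamber_id",
    temperature: str = "test_temperature",
    value: str = "injury",
) -> pd.DataFrame:
    """Population x chamber least-squares mean injury over the selected pair.

    Per chamber an additive two-way fixed-effects model
    (population + freeze treatment) is fit by least squares; a
    population's adjusted mean is its prediction averaged over the two
    treatments.  With balanced data this equals the simple mean over the
    two treatments.  Populations observed in neither selected treatment
    within a chamber are excluded from that chamber (logged) and
    reported as missing.

    Returns a DataFrame indexed by population with one column per chamber.
    """
    selected = [float(t) for t in selected]
    sub = injury[injury[temperature].isin(selected)]
    for t in selected:
        if t not in set(sub[temperature]):
            raise ValueError(f"selected temperature {t} not present in the injury table")
    cols = {}
    for ch, df in sub.groupby(chamber, sort=True):
        dropped = set(injury.loc[injury[chamber] == ch, population]) - set(df[population])
        if dropped:
            logger.warning(
                "chamber %s: populations %s have no data in the selected "
                "freeze treatments; excluded",
                ch,
                sorted(dropped),
            )
        cols[ch] = _ls_means_one_chamber(df, population, temperature, value)
    return pd.DataFrame(cols)
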