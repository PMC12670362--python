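"""Prediction-observation agreement metrics: RMSE, MBE and normalised forms.

The mean bias error MBE = mean(predicted - observed) is signed: positive
values indicate systematic overestimation by the model, negative values
underestimation.  RMSE = sqrt(mean((predicted - observed)^2)) bounds |MBE|
from above.  Normalised variants divide each metric by the mean observed
value of the trait, making traits with different units comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deb import DEBError, DEBParameters
from .simulate import LifeHistoryResult
from .synthetic import predict_treatments

TRAITS = ("mass", "age", "growth")
_TRAIT_COLUMNS = {"mass": "mass_ug", "age": "age_d", "growth": "growth_d"}
_TRAIT_ATTRS = {"mass": "mass_maturity", "age": "age_maturity_observed",
                "growth": "growth_rate_"}

TREATMENT_KEYS = ["tmean_C", "amplitude_C", "food_mgC_L", "quality"]


@dataclass(frozen=True)
class AgreementEntry:
    """Agreement metrics for one trait over one scope."""

    trait: str
    scope: str
    n: int
    rmse: float
    norm_rmse: float
    mbe: float
    norm_mbe: float


def agreement_metrics(predicted, observed, trait: str = "",
                      scope: str = "overall") -> AgreementEntry:
    """RMSE / MBE (and normalised forms) of paired predictions.

    Raises on empty pairings or a zero mean observed value (the normalised
    metrics would be undefined).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise DEBError("predicted and observed must be paired (equal length)")
    if predicted.size == 0:
        raise DEBError("empty pairing")
    err = predicted - observed
    mbe = float(np.mean(err))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mean_obs = float(np.mean(observed))
    if mean_obs == 0:
        raise DEBError("zero mean observed value; normalised metrics undefined")
    return AgreementEntry(trait, scope, predicted.size, rmse, rmse / mean_obs,
                          mbe, mbe / mean_obs)


def pair_predictions(
    predictions: dict[tuple, LifeHistoryResult],
    observed: pd.DataFrame,
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], pd.DataFrame]:
    """Pair every surviving observation with its treatment's prediction.

    Returns per-trait (predicted, observed) arrays plus the paired table
    (with prediction columns added) for per-treatment metrics.  Treatments
    where the model failed to mature contribute no numeric pairs; where the
    observations also record death this is agreement on failure, otherwise
    the rows are dropped as a recorded disagreement.

    Raises
    ------
    DEBError
        If the observed table is empty or references a treatment absent
        from the predictions.
    """
    if observed.empty:
        raise DEBError("observed table is empty")
    missing = [c for c in TREATMENT_KEYS + ["died"] if c not in observed.columns]
    if missing:
        raise DEBError(f"observed table lacks columns: {missing}")

    keys = list(observed[TREATMENT_KEYS].itertuples(index=False, name=None))
    unknown_rows = [i for i, k in enumerate(keys) if k not in predictions]
    if unknown_rows:
        raise DEBError(
            f"unknown treatment keys at rows {unknown_rows[:10]}"
            + ("..." if len(unknown_rows) > 10 else "")
        )

    alive = observed.loc[~observed["died"].astype(bool)].copy()
    alive_keys = list(alive[TREATMENT_KEYS].itertuples(index=False, name=None))
    model_ok = np.array([predictions[k].matured for k in alive_keys], dtype=bool)
    paired = alive.loc[model_ok].copy()
    paired_keys = [k for k, ok in zip(alive_keys, model_ok) if ok]
    for trait in TRAITS:
        paired[f"pred_{trait}"] = [
            getattr(predictions[k], _TRAIT_ATTRS[trait]) for k in paired_keys
        ]
    arrays = {
        trait: (paired[f"pred_{trait}"].to_numpy(),
                paired[_TRAIT_COLUMNS[trait]].to_numpy())
        for trait in TRAITS
    }
    return arrays, paired


def agreement_report(
    predictions: dict[tuple, LifeHistoryResult],
    observed: pd.DataFrame,
    by_jar: bool = False,
    norm_scope: str = "local",
) -> pd.DataFrame:
    """Full agreement report: overall and per-treatment, all three traits.

    Parameters
    ----------
    by_jar
        Aggregate observations to jar means before computing metrics.
    norm_scope
        ``"local"`` normalises each scope by its own mean observed value;
        ``"grand"`` always uses the overall mean.
    """
    if norm_scope not in ("local", "grand"):
        raise DEBError("norm_scope must be local|grand")
    arrays, paired = pair_predictions(predictions, observed)
    if by_jar:
        group_cols = TREATMENT_KEYS + ["jar"]
        num_cols = [c for c in paired.columns if c not in group_cols + ["individual", "died", "quality"]]
        paired = paired.groupby(TREATMENT_KEYS + ["jar"], as_index=False)[
            [c for c in num_cols if paired[c].dtype.kind in "fc"]].mean()

    entries: list[AgreementEntry] = []
    grand_means = {t: float(paired[_TRAIT_COLUMNS[t]].mean()) for t in TRAITS}
    for trait in TRAITS:
        pred = paired[f"pred_{trait}"].to_numpy()
        obs = paired[_TRAIT_COLUMNS[trait]].to_numpy()
        e = agreement_metrics(pred, obs, trait, "overall")
        entries.append(e)
        for key, grp in paired.groupby(TREATMENT_KEYS):
            scope = "T{:g}_A{:g}_X{:g}_{}".format(*key)
            e = agreement_metrics(grp[f"pred_{trait}"], grp[_TRAIT_COLUMNS[trait]],
                                  trait, scope)
            if norm_scope == "grand":
                e = AgreementEntry(trait, scope, e.n, e.rmse,
                                   e.rmse / grand_means[trait],
                                   e.mbe, e.mbe / grand_means[trait])
            entries.append(e)
    return pd.DataFrame([vars(e) for e in entries])


def compare_with_model(
    params: DEBParameters,
    observed: pd.DataFrame,
    by_jar: bool = False,
    norm_scope: str = "local",
) -> pd.DataFrame:
    """Convenience wrapper: predict all treatments, then report agreement."""
    return agreement_report(predict_treatments(params), observed,
                            by_jar=by_jar, norm_scope=norm_scope)
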