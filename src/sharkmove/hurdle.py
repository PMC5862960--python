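"""Hurdle-structured model-table assembly and model-selection helpers.

Receiver-array site-fidelity data are extremely zero-inflated (arrays
extend far beyond individual home ranges), so they are analysed as a
hurdle: a binary presence/absence component over all shark x receiver
pairs, and a proportional component (days detected vs days not detected)
over the non-zero pairs only. This module assembles those two model-ready
tables with centered/scaled predictors and a log-monitored-days offset,
screens predictors for collinearity (Pearson r, VIF), and ranks candidate
fits by small-sample AIC (AICc).

The mixed-model fits themselves (random effects for transmitter and
receiver station, smooth terms) are deliberately left to standard
statistical engines; a declarative model-specification record carries the
response, offset, fixed/random terms, and family so any such engine can be
invoked. Note the binomial-with-logit offset usage is emitted as specified
by the study design it mirrors, though an offset is unusual on the logit
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sharkmove.geo import haversine_km

CONTINUOUS_PREDICTORS = ("distance_km", "receiver_depth_m", "total_length_cm")


def build_predictors(sharks: pd.DataFrame, receivers: pd.DataFrame) -> pd.DataFrame:
    """Candidate predictors for every shark x receiver pair.

    ``sharks`` needs shark_id (or transmitter_id), sex, total_length_cm,
    island, lat, lon (tagging position); ``receivers`` needs receiver_id,
    lat, lon, depth_m, island. Continuous predictors (tagging-site ->
    receiver great-circle distance, receiver depth, total length) are
    mean-centered and scaled to unit SD; raw values are kept alongside and
    the centering constants in ``DataFrame.attrs['scaling']``.
    """
    for df, cols, what in (
        (sharks, ("sex", "total_length_cm", "island", "lat", "lon"), "shark"),
        (receivers, ("receiver_id", "lat", "lon", "depth_m", "island"), "receiver"),
    ):
        for c in cols:
            if c not in df.columns:
                raise ValueError(f"{what} table missing column {c!r}")
            if df[c].isna().any():
                bad = df.index[df[c].isna()][0]
                raise ValueError(f"missing {c!r} for {what} record {bad!r}")

    id_col = "transmitter_id" if "transmitter_id" in sharks.columns else "shark_id"
    rows = []
    for _, sh in sharks.iterrows():
        for _, rx in receivers.iterrows():
            rows.append(
                {
                    "transmitter_id": sh[id_col],
                    "receiver_id": rx["receiver_id"],
                    "distance_km": float(haversine_km(sh["lat"], sh["lon"], rx["lat"], rx["lon"])),
                    "receiver_depth_m": float(rx["depth_m"]),
                    "sex": sh["sex"],
                    "total_length_cm": float(sh["total_length_cm"]),
                    "tagging_island": sh["island"],
                    "receiver_island": rx["island"],
                }
            )
    table = pd.DataFrame(rows)
    scaling = {}
    for c in CONTINUOUS_PREDICTORS:
        mu, sd = table[c].mean(), table[c].std(ddof=1)
        table[c + "_z"] = (table[c] - mu) / sd if sd > 0 else 0.0
        scaling[c] = {"mean": float(mu), "sd": float(sd)}
    table.attrs["scaling"] = scaling
    return table


@dataclass
class HurdleTables:
    """Binary and proportional components of hurdle-structured SFI data."""

    binary: pd.DataFrame = field(repr=False)
    proportional: pd.DataFrame = field(repr=False)
    scaling: dict = field(default_factory=dict)

    @property
    def zero_inflation_pct(self) -> float:
        return 100.0 * (1.0 - len(self.proportional) / len(self.binary))


def hurdle_split(sfi: pd.DataFrame, predictors: pd.DataFrame) -> HurdleTables:
    """Split SFI records into hurdle components joined to predictors.

    The binary table has one row per pair: ``detected`` (0/1) and
    ``offset_log_days`` = log monitored days. The proportional table keeps
    only detected pairs, with ``days_detected`` and ``days_not_detected``
    (successes/failures out of the monitored days).
    """
    if (sfi["monitored_days"] <= 0).any():
        raise ValueError("all rows must have positive monitored days")
    if (sfi["days_detected"] < 0).any():
        raise ValueError("negative detection days")
    merged = sfi.merge(predictors, on=["transmitter_id", "receiver_id"], how="left")
    binary = merged.copy()
    binary["detected"] = (binary["days_detected"] > 0).astype(int)
    binary["offset_log_days"] = np.log(binary["monitored_days"].astype(float))
    prop = merged[merged["days_detected"] > 0].copy()
    prop["days_not_detected"] = prop["monitored_days"] - prop["days_detected"]
    return HurdleTables(binary, prop, dict(predictors.attrs.get("scaling", {})))


def reconstruct_sfi(tables: HurdleTables) -> pd.DataFrame:
    """Invert :func:`hurdle_split` (round-trip check)."""
    out = tables.binary[["transmitter_id", "receiver_id", "monitored_days"]].copy()
    prop = tables.proportional.set_index(["transmitter_id", "receiver_id"])["days_detected"]
    key = list(zip(out["transmitter_id"], out["receiver_id"]))
    out["days_detected"] = [int(prop.get(k, 0)) for k in key]
    out["sfi_pct"] = 100.0 * out["days_detected"] / out["monitored_days"]
    return out


def collinearity_screen(predictors: pd.DataFrame, columns=None):
    """Pearson correlation matrix and variance inflation factors.

    VIF_j = 1/(1 - R^2_j) where R^2_j comes from an ordinary least-squares
    regression (with intercept) of predictor j on the others. A singular
    design yields an infinite VIF with a flag column.
    """
    cols = list(columns) if columns is not None else [c + "_z" for c in CONTINUOUS_PREDICTORS]
    X = predictors[cols].to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two continuous predictors")
    if n <= p:
        raise ValueError("need more observations than predictors")
    corr = pd.DataFrame(np.corrcoef(X, rowvar=False), index=cols, columns=cols)

    rows = []
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, _, rank_, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 1.0
        singular = r2 >= 1.0 - 1e-12
        rows.append(
            {
                "predictor": cols[j],
                "vif": np.inf if singular else 1.0 / (1.0 - r2),
                "singular": bool(singular),
            }
        )
    return corr, pd.DataFrame(rows)


def rank_models_aicc(models: list[tuple[str, float, int, int]]) -> pd.DataFrame:
    """AICc model ranking with Akaike weights.

    ``models`` holds (name, log-likelihood, k parameters, n observations).
    AICc = -2*ll + 2k + 2k(k+1)/(n-k-1); models within delta < 2 of the best
    are flagged as substantially supported. Requires n > k + 1.
    """
    rows = []
    for name, ll, k, n in models:
        if n <= k + 1:
            raise ValueError(f"model {name!r}: need n > k + 1 (n={n}, k={k})")
        aicc = -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
        rows.append({"model": name, "log_lik": ll, "k": k, "n": n, "aicc": aicc})
    table = pd.DataFrame(rows)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    rel = np.exp(-table["delta_aicc"] / 2.0)
    table["akaike_weight"] = rel / rel.sum()
    table["substantial_support"] = table["delta_aicc"] < 2.0
    return table.sort_values("aicc", kind="stable").reset_index(drop=True)


@dataclass
class ModelSpec:
    """Declarative mixed-model specification for an external engine.

    Interactions must respect marginality: every interaction term's main
    effects must be present among the fixed terms.
    """

    response: str
    family: str
    link: str
    fixed: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    random: tuple[str, ...] = ("transmitter_id", "receiver_id")
    offset: str | None = None
    smooth_basis_k: int | None = None

    def __post_init__(self) -> None:
        for a, b in self.interactions:
            if a not in self.fixed or b not in self.fixed:
                raise ValueError(
                    f"interaction ({a}, {b}) violates marginality: both main effects required"
                )

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "family": self.family,
            "link": self.link,
            "fixed": list(self.fixed),
            "interactions": [list(i) for i in self.interactions],
            "random": list(self.random),
            "offset": self.offset,
            "smooth_basis_k": self.smooth_basis_k,
        }


def default_model_specs() -> dict[str, ModelSpec]:
    """The canonical binary and proportional hurdle model specifications."""
    fixed = ("distance_km_z", "receiver_depth_m_z", "sex", "total_length_cm_z", "tagging_island")
    return {
        "binary": ModelSpec(
            response="detected",
            family="binomial",
            link="logit",
            fixed=fixed,
            interactions=(("sex", "receiver_depth_m_z"), ("distance_km_z", "receiver_depth_m_z")),
            offset="offset_log_days",
        ),
        "proportional": ModelSpec(
            response="cbind(days_detected, days_not_detected)",
            family="binomial",
            link="logit",
            fixed=fixed,
            smooth_basis_k=5,
        ),
    }
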