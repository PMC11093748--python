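"""Enrichment scoring and hit calling for pooled SABR screens.

The screen compares sorted (reporter-positive, top-gate) samples against
unsorted library samples. For each sorted replicate, an ordinary
least-squares model of normalized sorted abundance on mean normalized
unsorted abundance predicts the expected abundance of every epitope; the
enrichment score is the residual

    ES(epitope) = observed - expected        (counts-per-million units)

averaged across the replicates in which a TCR was present. Two-tier
confidence zones are calibrated from a positive-control TCR whose cognate
epitopes are known: the thresholds are fixed fractions of the weakest control
cognate's mean ES. Dropout deconvolution extends this to multiplexed
leave-one-out designs: each replicate omits one TCR from the co-incubation,
and a TCR's score is the mean ES over the replicates that contained it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .read_processing import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScreenDesign:
    """Which samples are what: unsorted references, sorted replicates and the
    TCRs each sorted co-incubation contained, plus the calibration control."""

    unsorted: list[str]
    sorted_tcrs: dict[str, frozenset]  # sorted sample_id -> TCR labels present
    control_tcr: str | None = None
    control_cognates: frozenset = frozenset()

    def __post_init__(self):
        if not self.unsorted:
            raise ValueError("design requires >= 1 unsorted sample")
        self.sorted_tcrs = {s: frozenset(t) for s, t in self.sorted_tcrs.items()}
        for s, tcrs in self.sorted_tcrs.items():
            if not tcrs:
                raise ValueError(f"sorted sample {s} lists no TCRs")

    @property
    def tcrs(self) -> list[str]:
        return sorted(set().union(*self.sorted_tcrs.values()))

    def samples_with(self, tcr: str) -> list[str]:
        return [s for s, tcrs in self.sorted_tcrs.items() if tcr in tcrs]

    def samples_without(self, tcr: str) -> list[str]:
        return [s for s, tcrs in self.sorted_tcrs.items() if tcr not in tcrs]

    def validate_against(self, matrix: CountMatrix) -> None:
        missing = (set(self.unsorted) | set(self.sorted_tcrs)) - set(matrix.counts.columns)
        if missing:
            raise ValueError(f"design samples absent from count matrix: {sorted(missing)}")

    def to_json(self, path) -> None:
        payload = {
            "unsorted": self.unsorted,
            "sorted_tcrs": {s: sorted(t) for s, t in self.sorted_tcrs.items()},
            "control_tcr": self.control_tcr,
            "control_cognates": sorted(self.control_cognates),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScreenDesign":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            unsorted=d["unsorted"],
            sorted_tcrs={s: frozenset(t) for s, t in d["sorted_tcrs"].items()},
            control_tcr=d.get("control_tcr"),
            control_cognates=frozenset(d.get("control_cognates", [])),
        )


@dataclass
class AbundanceModel:
    """Fitted linear relation between unsorted and sorted abundance."""

    slope: float
    intercept: float
    r_squared: float
    resid_sd: float
    covariate: pd.Series = field(repr=False, default=None)

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class ConfidenceZones:
    """Two-tier ES cutoffs calibrated from control cognate scores."""

    high_threshold: float
    low_threshold: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.high_threshold >= self.low_threshold > 0:
            raise ValueError("zones require high_threshold >= low_threshold > 0")

    def tier(self, mean_es: float) -> str:
        if mean_es >= self.high_threshold:
            return "high"
        if mean_es >= self.low_threshold:
            return "low"
        return "none"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "high_threshold": self.high_threshold,
                    "low_threshold": self.low_threshold,
                    "provenance": self.provenance,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def normalize(matrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Counts-per-million per sample after adding a pseudocount to every cell.

    Accepts a :class:`CountMatrix` or a raw counts DataFrame. An all-zero
    column is an error naming the sample.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    zero = counts.columns[counts.sum(axis=0) == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero)}")
    shifted = counts.astype(float) + pseudocount
    return shifted / shifted.sum(axis=0) * 1e6


def fit_expected_abundance(unsorted: pd.DataFrame, sorted_col: pd.Series) -> AbundanceModel:
    """OLS (with intercept) of a sorted sample's normalized abundance on the
    mean normalized unsorted abundance; expected(e) = intercept + slope * x(e)."""
    x = unsorted.mean(axis=1)
    y = sorted_col.reindex(x.index)
    if len(x) < 3:
        raise ValueError("abundance model requires >= 3 epitopes")
    if float(np.var(x.values)) == 0.0:
        raise ValueError("zero variance in unsorted abundance covariate")
    fit = sm.OLS(y.values, sm.add_constant(x.values)).fit()
    resid_sd = float(np.std(fit.resid, ddof=2)) if len(x) > 2 else 0.0
    return AbundanceModel(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        resid_sd=resid_sd,
        covariate=x,
    )


class EnrichmentScorer(BaseEstimator):
    """Per-replicate residual enrichment scoring over a screen design.

    Parameters
    ----------
    pseudocount : float, default 0.5
        Added to every count before counts-per-million normalization, taming
        zero counts before the regression.
    studentize : bool, default False
        Divide each replicate's residuals by that fit's residual SD, yielding
        unitless scores instead of CPM residuals.

    Attributes (after :meth:`fit`)
    ------------------------------
    abundance_ : DataFrame, normalized abundance per sample.
    covariate_ : Series, mean unsorted abundance per epitope.
    models_ : dict sorted sample -> :class:`AbundanceModel`.
    es_ : DataFrame epitope x sorted sample of residual scores.
    expected_ : DataFrame epitope x sorted sample of model predictions.
    tcr_scores_ : DataFrame epitope x TCR of mean ES over the replicates
        containing that TCR.
    """

    def __init__(self, pseudocount: float = 0.5, studentize: bool = False):
        self.pseudocount = pseudocount
        self.studentize = studentize

    def fit(self, matrix: CountMatrix, design: ScreenDesign, library=None):
        design.validate_against(matrix)
        counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
        if library is not None:
            known = {e.id for e in library.epitopes}
            extra = [e for e in counts.index if e not in known]
            if extra:
                logger.warning(
                    "excluding %d epitope(s) absent from the library manifest: %s",
                    len(extra), extra[:5],
                )
                counts = counts.drop(index=extra)
        self.design_ = design
        self.abundance_ = normalize(counts, self.pseudocount)
        self.covariate_ = self.abundance_[design.unsorted].mean(axis=1)
        self.models_ = {}
        es = {}
        expected = {}
        for s in design.sorted_tcrs:
            model = fit_expected_abundance(self.abundance_[design.unsorted], self.abundance_[s])
            pred = pd.Series(model.predict(self.covariate_), index=self.covariate_.index)
            resid = self.abundance_[s] - pred
            if self.studentize:
                if model.resid_sd == 0:
                    raise ValueError(f"zero residual SD for sample {s}; cannot studentize")
                resid = resid / model.resid_sd
            self.models_[s] = model
            expected[s] = pred
            es[s] = resid
        self.expected_ = pd.DataFrame(expected)
        self.es_ = pd.DataFrame(es)
        self.tcr_scores_ = pd.DataFrame(
            {t: self.es_[design.samples_with(t)].mean(axis=1) for t in design.tcrs}
        )
        return self

    def mean_es(self, tcr: str) -> pd.Series:
        return self.tcr_scores_[tcr]

    def es_table(self, tcr: str, zones: "ConfidenceZones | None" = None) -> pd.DataFrame:
        """Tidy per-epitope table for one TCR: observed/expected per replicate
        mean, replicate ES columns, mean ES and (optionally) tier."""
        samples = self.design_.samples_with(tcr)
        out = pd.DataFrame(
            {
                "observed": self.abundance_[samples].mean(axis=1),
                "expected": self.expected_[samples].mean(axis=1),
            }
        )
        for s in samples:
            out[f"es_{s}"] = self.es_[s]
        out["mean_es"] = self.tcr_scores_[tcr]
        if zones is not None:
            out["tier"] = [zones.tier(v) for v in out["mean_es"]]
        return out.sort_values("mean_es", ascending=False)


def compute_es(design: ScreenDesign, matrix: CountMatrix, pseudocount: float = 0.5,
               studentize: bool = False, library=None) -> EnrichmentScorer:
    """Fit the per-replicate abundance models and residual ES for a screen."""
    return EnrichmentScorer(pseudocount=pseudocount, studentize=studentize).fit(
        matrix, design, library=library
    )


def calibrate_zones(control_mean_es: pd.Series, cognates,
                    fractions: tuple[float, float] = (0.5, 0.25)) -> ConfidenceZones:
    """Set two-tier thresholds from the control TCR's cognate ES values.

    base = min mean ES over control cognates; high = f_high*base,
    low = f_low*base. A control cognate with non-positive mean ES indicates a
    failed screen and raises.
    """
    cognates = sorted(cognates)
    if not cognates:
        raise ValueError("no control cognates supplied")
    missing = [c for c in cognates if c not in control_mean_es.index]
    if missing:
        raise ValueError(f"control cognates absent from results: {missing}")
    values = control_mean_es.loc[cognates]
    if (values <= 0).any():
        bad = values[values <= 0]
        raise ValueError(
            f"control cognate(s) with non-positive mean ES (failed screen signal): "
            f"{dict(bad.round(3))}"
        )
    f_high, f_low = fractions
    base = float(values.min())
    return ConfidenceZones(
        high_threshold=f_high * base,
        low_threshold=f_low * base,
        provenance={
            "control_cognate_es": {c: float(v) for c, v in values.items()},
            "base": base,
            "fractions": [f_high, f_low],
        },
    )


def call_hits(mean_es: pd.Series, zones: ConfidenceZones) -> pd.DataFrame:
    """Two-tier hit list: epitopes with mean ES in a confidence zone, sorted by
    descending mean ES then epitope id."""
    df = pd.DataFrame({"mean_es": mean_es})
    df["tier"] = [zones.tier(v) for v in df["mean_es"]]
    hits = df[df["tier"] != "none"].copy()
    return hits.loc[
        sorted(hits.index, key=lambda e: (-hits.at[e, "mean_es"], str(e)))
    ]


def dropout_deconvolute(design: ScreenDesign, matrix: CountMatrix,
                        contrast: bool = False, pseudocount: float = 0.5,
                        studentize: bool = False) -> pd.DataFrame:
    """Score TCRs from a multiplexed leave-one-out (dropout) screen.

    Plain mode: score(tcr, e) = mean ES over sorted replicates whose TCR set
    contains `tcr`. Contrast mode additionally subtracts the mean ES over
    replicates lacking the TCR (requires each TCR to be absent from at least
    one replicate).

    Returns a DataFrame epitope x TCR of scores; hit calling proceeds with
    :func:`calibrate_zones` / :func:`call_hits` per TCR as usual.
    """
    scorer = compute_es(design, matrix, pseudocount=pseudocount, studentize=studentize)
    scores = {}
    for tcr in design.tcrs:
        present = scorer.es_[design.samples_with(tcr)].mean(axis=1)
        if contrast:
            absent_samples = design.samples_without(tcr)
            if not absent_samples:
                raise ValueError(
                    f"TCR {tcr!r} present in every replicate; contrast mode impossible"
                )
            present = present - scorer.es_[absent_samples].mean(axis=1)
        scores[tcr] = present
    return pd.DataFrame(scores)
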