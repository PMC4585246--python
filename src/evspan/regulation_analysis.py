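"""EVS regulation analyses: binned probability curves, orthogonal
polynomial contrasts, logistic fits, and single-fixation-duration
model frames.

The binomial outcomes (regression out, refixation) are modelled with a
logit link as polynomial functions of the spatial EVS; single fixation
durations are modelled on the log scale with the standard word-property
and oculomotor covariates of the fixated word and its neighbours.
Random effects for subjects and sentences are deliberately not
estimated here: frames carry the grouping columns so they can be
exported to a mixed-model package, and fixed-effects analogues are
fitted in-package.  Effects with |t| or |z| above 2.0 are flagged as
significant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PolyTerm",
    "GLMFit",
    "binned_curve",
    "orthopoly",
    "build_design",
    "fit_logistic",
    "build_sfd_frame",
    "fit_loglinear_sfd",
]

#: |t| / |z| threshold used to flag significant effects
SIGNIFICANCE_T = 2.0


@dataclass(frozen=True)
class PolyTerm:
    """A covariate entered as a polynomial of given degree.

    By default the columns are an orthonormal polynomial basis; with
    ``raw=True`` plain powers of the untransformed covariate are used
    instead (coefficients then live on the covariate's own scale).
    """

    column: str
    degree: int = 1
    raw: bool = False


@dataclass
class GLMFit:
    """Result of an in-package GLM/OLS fit."""

    names: list[str]
    estimates: np.ndarray
    standard_errors: np.ndarray
    z_values: np.ndarray
    deviance: float
    iterations: int
    converged: bool
    message: str = ""

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.estimates,
                "se": self.standard_errors,
                "z": self.z_values,
                "significant": np.abs(self.z_values) > SIGNIFICANCE_T,
            }
        )


def binned_curve(
    x, y, n_bins: int = 10
) -> pd.DataFrame:
    """Equal-count (quantile) binned proportions of a binary outcome.

    Returns one row per bin with the bin's mean ``x`` (center), the
    outcome proportion, the count, and a Wilson 95% interval.  If there
    are fewer distinct ``x`` values than requested bins the bin count is
    reduced with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    n_distinct = np.unique(x).size
    if n_distinct < n_bins:
        warnings.warn(
            f"only {n_distinct} distinct x values; reducing bin count",
            stacklevel=2,
        )
        n_bins = max(2, n_distinct)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        m = idx == b
        cnt = int(m.sum())
        if cnt == 0:
            continue
        k = int(y[m].sum())
        lo, hi = proportion_confint(k, cnt, alpha=0.05, method="wilson")
        rows.append(
            {
                "center": float(x[m].mean()),
                "proportion": k / cnt,
                "count": cnt,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def orthopoly(x, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis over the observed values.

    Columns 1..degree are mutually orthogonal with unit norm and
    orthogonal to the constant; the sign is fixed so each column's
    leading (highest-power) coefficient is positive, matching the usual
    orthogonal-contrast convention up to that sign choice.
    """
    x = np.asarray(x, dtype=float)
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    if np.unique(x).size < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct values for degree {degree}"
        )
    xc = (x - x.mean()) / max(x.std(), np.finfo(float).tiny)  # conditioning only
    V = np.vander(xc, degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    return Q[:, 1:]


def build_design(
    frame: pd.DataFrame,
    terms: list[PolyTerm],
    interactions_with: str | None = None,
) -> pd.DataFrame:
    """Design matrix with intercept, orthonormal polynomial columns, and
    optional interactions of every term with one linear covariate.

    Interaction columns are elementwise products of the (centered)
    moderator with each polynomial column.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(frame))}
    for t in terms:
        x = frame[t.column].to_numpy(dtype=float)
        if t.raw:
            basis = np.column_stack([x ** (d + 1) for d in range(t.degree)])
        else:
            basis = orthopoly(x, t.degree)
        for d in range(t.degree):
            name = t.column if t.degree == 1 else f"{t.column}^{d + 1}"
            cols[name] = basis[:, d]
    if interactions_with is not None:
        mod = frame[interactions_with].to_numpy(dtype=float)
        mod = mod - mod.mean()
        for name in list(cols):
            if name == "intercept" or name.startswith(interactions_with):
                continue
            cols[f"{interactions_with}:{name}"] = mod * cols[name]
    return pd.DataFrame(cols, index=frame.index)


def fit_logistic(
    frame: pd.DataFrame,
    outcome: str,
    terms: list[PolyTerm] | None = None,
    design: pd.DataFrame | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> GLMFit:
    """Maximum-likelihood logistic regression by IRLS.

    Convergence: relative deviance change below ``tol`` within
    ``max_iter`` iterations.  Standard errors come from the final
    weighted least-squares system.  Complete separation is reported via
    ``converged=False`` with a diagnostic message rather than silently
    returning huge coefficients.
    """
    y = frame[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    if design is None:
        design = build_design(frame, terms or [])
    X = design.to_numpy(dtype=float)
    names = list(design.columns)
    n, p = X.shape
    beta = np.zeros(p)
    dev_old = math.inf
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = X @ beta
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        dev = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        if abs(dev_old - dev) / (abs(dev) + 0.1) < tol:
            converged = True
            break
        dev_old = dev
    # |eta| > 18.4 puts a fitted probability within 1e-8 of 0/1
    if np.max(np.abs(X @ beta)) > 18.0:
        converged = False
        message = (
            "possible complete separation: fitted probabilities within 1e-8 of 0/1"
        )
    elif not converged:
        message = f"IRLS did not converge in {max_iter} iterations"
    mu = np.clip(1.0 / (1.0 + np.exp(-(X @ beta))), 1e-12, 1 - 1e-12)
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = beta / se
    return GLMFit(
        names=names,
        estimates=beta,
        standard_errors=se,
        z_values=zvals,
        deviance=dev,
        iterations=it,
        converged=converged,
        message=message,
    )


#: covariates of the single-fixation-duration model frame
SFD_COVARIATES = [
    "length_prev",
    "log_freq_prev",
    "pred_prev",
    "length_n",
    "log_freq_n",
    "pred_n",
    "length_next",
    "log_freq_next",
    "pred_next",
    "launch_site",
    "landing_site",
    "outgoing_saccade",
]


def build_sfd_frame(
    word_frame: pd.DataFrame,
    corpus: pd.DataFrame,
    include_evs: bool = True,
    center: bool = True,
) -> pd.DataFrame:
    """Assemble the single-fixation-duration model frame.

    ``word_frame`` has one row per word per trial (the tidy export of
    the first-pass parser merged with per-word EVS), with columns
    ``subject_id, trial_id, sentence_id, word_index, sfd,
    launch_site_letters, landing_site_letters, outgoing_saccade_letters,
    excluded`` and, when ``include_evs``, ``onset_evs`` and
    ``delta_evs``.  ``corpus`` has ``sentence_id, word_index, word,
    frequency_per_million, predictability``.

    Rows are single-fixation, non-excluded words whose two neighbours
    exist in the corpus; the outcome is the natural log of SFD;
    frequencies are log10-transformed; covariates are mean-centered
    when ``center``.  Rows with any missing fitted column are dropped.
    """
    corpus = corpus.copy()
    corpus["length"] = corpus["word"].astype(str).str.len()
    corpus["log_freq"] = np.log10(corpus["frequency_per_million"].astype(float))
    props = corpus.set_index(["sentence_id", "word_index"])

    rows = []
    for r in word_frame.itertuples():
        if getattr(r, "excluded", False) or not (r.sfd == r.sfd) :
            continue
        sent = r.sentence_id
        w = int(r.word_index)
        try:
            pn = props.loc[(sent, w)]
            pp = props.loc[(sent, w - 1)]
            pq = props.loc[(sent, w + 1)]
        except KeyError:
            continue  # sentence-edge: neighbour properties missing
        row = {
            "subject_id": r.subject_id,
            "trial_id": r.trial_id,
            "sentence_id": sent,
            "word_index": w,
            "log_sfd": math.log(r.sfd),
            "length_prev": float(pp["length"]),
            "log_freq_prev": float(pp["log_freq"]),
            "pred_prev": float(pp["predictability"]),
            "length_n": float(pn["length"]),
            "log_freq_n": float(pn["log_freq"]),
            "pred_n": float(pn["predictability"]),
            "length_next": float(pq["length"]),
            "log_freq_next": float(pq["log_freq"]),
            "pred_next": float(pq["predictability"]),
            "launch_site": float(r.launch_site_letters),
            "landing_site": float(r.landing_site_letters),
            "outgoing_saccade": float(r.outgoing_saccade_letters),
        }
        if include_evs:
            row["onset_evs"] = float(getattr(r, "onset_evs", math.nan))
            row["delta_evs"] = float(getattr(r, "delta_evs", math.nan))
        rows.append(row)
    frame = pd.DataFrame(rows)
    fitted = SFD_COVARIATES + (["onset_evs", "delta_evs"] if include_evs else [])
    if len(frame):
        frame = frame.dropna(subset=[c for c in fitted if c in frame.columns] + ["log_sfd"])
        frame = frame.reset_index(drop=True)
    if center and len(frame):
        means = {}
        for c in fitted:
            if c in frame.columns:
                means[c] = float(frame[c].mean())
                frame[c] = frame[c] - means[c]
        frame.attrs["centering_means"] = means
    return frame


def fit_loglinear_sfd(
    frame: pd.DataFrame,
    terms: list[PolyTerm] | None = None,
    interactions_with: str | None = "onset_evs",
) -> GLMFit:
    """Fixed-effects least squares on log SFD with polynomial covariates
    and optional EVS × covariate interactions.

    The default term set mirrors the standard single-fixation model:
    quadratic trends for all covariates except the fixated word's
    frequency, which gets a cubic trend.  Raises on rank deficiency,
    naming the aliased columns.
    """
    if terms is None:
        terms = [
            PolyTerm(c, 3 if c == "log_freq_n" else 2) for c in SFD_COVARIATES
        ]
        if interactions_with and interactions_with in frame.columns:
            terms = terms + [PolyTerm(interactions_with, 1)]
    design = build_design(frame, terms, interactions_with=interactions_with)
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        aliased = [design.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    model = sm.OLS(frame["log_sfd"].to_numpy(dtype=float), X)
    res = model.fit()
    return GLMFit(
        names=list(design.columns),
        estimates=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        z_values=np.asarray(res.tvalues),
        deviance=float(res.ssr),
        iterations=1,
        converged=True,
    )
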