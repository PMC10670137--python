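"""Event-level statistics: Welch t-tests and a random-intercept mixed model.

The unit of analysis is one kept event summary (the mean normalized change
of one signal over the 6 s post-stimulus window); events are pooled across
subjects for the two-sample tests, mirroring designs whose event counts
far exceed subject counts. For subjects measured under both theta-burst
paradigms, a linear mixed model

    change ~ condition (pre / cTBS / iTBS) + (1 | subject)

fitted by REML compares the conditions within subject; the cTBS-vs-iTBS
contrast comes from refitting with the reference level moved. No
multiplicity adjustment is applied; all p-values are reported unadjusted.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import SIGNALS

logger = logging.getLogger(__name__)

ALPHA = 0.05
CONDITION_LEVELS = ("pre", "cTBS", "iTBS")


@dataclass
class ComparisonResult:
    """Welch two-sample test between two groups of event summaries."""

    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float


def welch_test(values_a, values_b) -> ComparisonResult:
    """Two-sided Welch t-test with Satterthwaite degrees of freedom.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b). Degenerate
    zero-variance inputs: identical constant groups give t = 0, p = 1;
    otherwise the df is clamped to its lower bound min(n_a, n_b) - 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must be finite")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    qa, qb = va / na, vb / nb
    se2 = qa + qb
    df_lower = float(min(na, nb) - 1)
    if se2 == 0.0:
        if ma == mb:
            return ComparisonResult(na, nb, float(ma), float(mb), 0.0, df_lower, 1.0)
        t = np.inf if ma > mb else -np.inf
        return ComparisonResult(na, nb, float(ma), float(mb), float(t), df_lower, 0.0)
    denom = qa**2 / (na - 1) + qb**2 / (nb - 1)
    df = se2**2 / denom if denom > 0 else df_lower
    df = max(df, df_lower)
    t = (ma - mb) / np.sqrt(se2)
    p = 2.0 * sps.t.sf(abs(t), df)
    return ComparisonResult(na, nb, float(ma), float(mb), float(t), float(df), float(p))


@dataclass
class LMMResult:
    """Random-intercept mixed-model fit for one signal x modality."""

    signal: str
    modality: str
    effects: pd.DataFrame  # columns: contrast, estimate_pct, se, p
    random_intercept_sd: float
    residual_sd: float
    n_obs: int
    n_subjects: int
    loglike: float
    converged: bool
    singular: bool
    pvalue_method: str = "wald-normal"


def _mixedlm_fit(data: pd.DataFrame, reference: str):
    import statsmodels.formula.api as smf

    formula = f"value ~ C(condition, Treatment('{reference}'))"
    model = smf.mixedlm(formula, data=data, groups=data["subject"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
        fit.llf  # force evaluation while degenerate-fit warnings are muted
    return fit


def _contrast_rows(fit, reference: str, levels, pvalue_method: str, data: pd.DataFrame):
    rows = []
    for level in levels:
        if level == reference:
            continue
        name = f"C(condition, Treatment('{reference}'))[T.{level}]"
        if name not in fit.params.index:
            continue
        est = float(fit.params[name])
        se = float(fit.bse[name])
        if pvalue_method == "conditional-t":
            # nlme-style within-group denominator df
            n_groups = data["subject"].nunique()
            dendf = max(len(data) - n_groups - (len(levels) - 1), 1)
            p = 2.0 * sps.t.sf(abs(est / se), dendf) if se > 0 else np.nan
        else:
            p = 2.0 * sps.norm.sf(abs(est / se)) if se > 0 else np.nan
        rows.append(
            {"contrast": f"{level} - {reference}", "estimate_pct": est, "se": se, "p": float(p)}
        )
    return rows


def fit_lmm(
    summaries: pd.DataFrame,
    signal: str,
    modality: str = "real",
    *,
    pvalue_method: str = "wald-normal",
) -> LMMResult:
    """Fit change ~ condition with a Gaussian random intercept per subject.

    ``summaries`` rows must carry subject, paradigm, epoch, modality,
    signal, kept, mean_normalized_change_pct. Pre-TBS events (either
    paradigm) form the reference level; post events are labelled by their
    paradigm. Only subjects observed under both paradigms enter. A fit with
    (numerically) zero between-subject variance is flagged ``singular`` —
    it reduces to pooled OLS — and the estimates are still returned.
    """
    if pvalue_method not in ("wald-normal", "conditional-t"):
        raise ValueError("pvalue_method must be 'wald-normal' or 'conditional-t'")
    df = summaries[
        (summaries["signal"] == signal)
        & (summaries["modality"] == modality)
        & summaries["kept"]
    ].copy()
    both = df.groupby("subject")["paradigm"].nunique()
    crossover_subjects = both[both >= 2].index
    df = df[df["subject"].isin(crossover_subjects)]
    if df["subject"].nunique() < 2:
        raise ValueError("mixed model needs >= 2 subjects measured under both paradigms")
    df["condition"] = np.where(df["epoch"] == "pre", "pre", df["paradigm"])
    df = df.rename(columns={"mean_normalized_change_pct": "value"})[
        ["subject", "condition", "value"]
    ]
    levels = [lv for lv in CONDITION_LEVELS if lv in set(df["condition"])]
    if len(levels) < 2:
        raise ValueError("mixed model needs >= 2 condition levels")

    fit = _mixedlm_fit(df, reference="pre")
    rows = _contrast_rows(fit, "pre", levels, pvalue_method, df)
    if "cTBS" in levels and "iTBS" in levels:
        refit = _mixedlm_fit(df, reference="cTBS")
        rows += [
            r for r in _contrast_rows(refit, "cTBS", levels, pvalue_method, df)
            if r["contrast"] == "iTBS - cTBS"
        ]
    re_var = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    singular = re_var <= 1e-10
    return LMMResult(
        signal=signal,
        modality=modality,
        effects=pd.DataFrame(rows),
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        residual_sd=float(np.sqrt(fit.scale)),
        n_obs=int(len(df)),
        n_subjects=int(df["subject"].nunique()),
        loglike=float(fit.llf),
        converged=bool(fit.converged),
        singular=singular,
        pvalue_method=pvalue_method,
    )


def _values(df: pd.DataFrame, signal: str, modality=None, epoch=None, paradigm=None):
    m = (df["signal"] == signal) & df["kept"]
    if modality is not None:
        m &= df["modality"] == modality
    if epoch is not None:
        m &= df["epoch"] == epoch
    if paradigm is not None:
        m &= df["paradigm"] == paradigm
    return df.loc[m, "mean_normalized_change_pct"].to_numpy()


@dataclass
class EvokedContrastResults:
    """Contrast matrix over conditions plus the mixed-model table."""

    contrasts: pd.DataFrame
    lmm: dict = field(default_factory=dict)  # (signal, modality) -> LMMResult
    pre_pooled: dict = field(default_factory=dict)  # signal -> bool
    alpha: float = ALPHA

    def summary(self) -> str:
        lines = ["Evoked-response contrasts (Welch two-sample tests, unadjusted p)",
                 "=" * 68]
        with pd.option_context("display.width", 120, "display.max_rows", 200):
            lines.append(self.contrasts.to_string(index=False))
        for (signal, modality), res in self.lmm.items():
            lines += [
                "",
                f"Linear mixed model — {signal}, {modality} stimuli "
                f"({res.n_obs} events, {res.n_subjects} subjects"
                f"{', singular random intercept' if res.singular else ''})",
                res.effects.to_string(index=False),
                f"random intercept SD {res.random_intercept_sd:.3f}, "
                f"residual SD {res.residual_sd:.3f}",
            ]
        lines.append("")
        lines.append("p-values are unadjusted for multiplicity.")
        return "\n".join(lines)

    def to_report(self) -> dict:
        report = {
            "alpha": self.alpha,
            "pre_pooled": dict(self.pre_pooled),
            "contrasts": self.contrasts.to_dict(orient="records"),
            "lmm": {
                f"{sig}|{mod}": {
                    "effects": res.effects.to_dict(orient="records"),
                    "random_intercept_sd": res.random_intercept_sd,
                    "residual_sd": res.residual_sd,
                    "n_obs": res.n_obs,
                    "n_subjects": res.n_subjects,
                    "singular": res.singular,
                    "converged": res.converged,
                    "pvalue_method": res.pvalue_method,
                }
                for (sig, mod), res in self.lmm.items()
            },
            "note": "p-values unadjusted",
        }
        return report

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_report(), fh, indent=2)

    def plot_means(self, ax=None):
        """Bar plot of group means with standard-error bars per signal."""
        import matplotlib.pyplot as plt

        df = self.contrasts
        cells = {}
        for _, row in df.iterrows():
            for side in ("a", "b"):
                label = row[f"group_{side}"]
                cells.setdefault((row["signal"], label), (row[f"mean_{side}"],
                                                          row[f"se_{side}"]))
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        labels = sorted(cells)
        xs = np.arange(len(labels))
        means = [cells[k][0] for k in labels]
        ses = [cells[k][1] for k in labels]
        ax.bar(xs, means, yerr=ses, capsize=3)
        ax.set_xticks(xs)
        ax.set_xticklabels([f"{s}\n{g}" for s, g in labels], fontsize=7)
        ax.set_ylabel("mean normalized change (%)")
        ax.axhline(0, color="k", lw=0.5)
        return ax


class EvokedContrastModel:
    """Builds the full condition-contrast table from kept event summaries.

    Pre-TBS events are pooled across paradigms only if neither the
    real-vs-real nor the sham-vs-sham pre-paradigm comparison is
    significant at ``alpha`` (checked per signal); otherwise they stay
    separate and a warning is logged.
    """

    def __init__(self, summaries: pd.DataFrame, alpha: float = ALPHA):
        required = {
            "subject", "paradigm", "epoch", "modality", "signal",
            "mean_normalized_change_pct", "kept",
        }
        missing = required - set(summaries.columns)
        if missing:
            raise ValueError(f"summaries missing columns: {sorted(missing)}")
        self.summaries = summaries
        self.alpha = float(alpha)

    def _welch_row(self, signal, name, va, label_a, vb, label_b):
        if va.size < 2 or vb.size < 2:
            logger.info("skipping contrast %s / %s: empty or tiny cell", signal, name)
            return None
        r = welch_test(va, vb)
        return {
            "signal": signal,
            "contrast": name,
            "group_a": label_a,
            "group_b": label_b,
            "n_a": r.n_a, "n_b": r.n_b,
            "mean_a": r.mean_a, "mean_b": r.mean_b,
            "se_a": float(np.std(va, ddof=1) / np.sqrt(r.n_a)),
            "se_b": float(np.std(vb, ddof=1) / np.sqrt(r.n_b)),
            "t": r.t, "df": r.df, "p": r.p,
        }

    def fit(self) -> EvokedContrastResults:
        df = self.summaries
        rows = []
        pre_pooled = {}
        for signal in SIGNALS:
            # pooling gate on the pre-TBS epoch
            pool = True
            for modality in ("real", "sham"):
                va = _values(df, signal, modality, "pre", "cTBS")
                vb = _values(df, signal, modality, "pre", "iTBS")
                if va.size >= 2 and vb.size >= 2:
                    if welch_test(va, vb).p < self.alpha:
                        pool = False
            if not pool:
                logger.warning(
                    "pre-TBS %s differs between paradigm sessions; not pooling", signal
                )
            pre_pooled[signal] = pool

            def pre(modality, paradigm):
                if pool:
                    return _values(df, signal, modality, "pre"), "pre (pooled)"
                return (
                    _values(df, signal, modality, "pre", paradigm),
                    f"pre ({paradigm} session)",
                )

            # real vs sham within each epoch/paradigm
            if pool:
                va, la = pre("real", None)
                vb, lb = pre("sham", None)
                rows.append(self._welch_row(signal, "real vs sham, pre-TBS",
                                            va, "real " + la, vb, "sham " + lb))
            else:
                for par in ("cTBS", "iTBS"):
                    va, la = pre("real", par)
                    vb, lb = pre("sham", par)
                    rows.append(self._welch_row(
                        signal, f"real vs sham, pre-TBS ({par} session)",
                        va, "real " + la, vb, "sham " + lb))
            for par in ("cTBS", "iTBS"):
                rows.append(self._welch_row(
                    signal, f"real vs sham, post-{par}",
                    _values(df, signal, "real", "post", par), f"real post-{par}",
                    _values(df, signal, "sham", "post", par), f"sham post-{par}"))
            # across paradigms, post
            for modality in ("real", "sham"):
                rows.append(self._welch_row(
                    signal, f"{modality}: post-cTBS vs post-iTBS",
                    _values(df, signal, modality, "post", "cTBS"),
                    f"{modality} post-cTBS",
                    _values(df, signal, modality, "post", "iTBS"),
                    f"{modality} post-iTBS"))
            # post vs pre for each paradigm/modality
            for par in ("cTBS", "iTBS"):
                for modality in ("real", "sham"):
                    vpre, lpre = pre(modality, par)
                    rows.append(self._welch_row(
                        signal, f"{modality}: post-{par} vs pre-TBS",
                        _values(df, signal, modality, "post", par),
                        f"{modality} post-{par}",
                        vpre, f"{modality} {lpre}"))

        contrasts = pd.DataFrame([r for r in rows if r is not None])

        lmm = {}
        for signal in SIGNALS:
            for modality in ("real", "sham"):
                try:
                    lmm[(signal, modality)] = fit_lmm(df, signal, modality)
                except ValueError as exc:
                    logger.info("LMM skipped for %s/%s: %s", signal, modality, exc)
        return EvokedContrastResults(
            contrasts=contrasts, lmm=lmm, pre_pooled=pre_pooled, alpha=self.alpha
        )


def run_comparisons(summaries: pd.DataFrame, alpha: float = ALPHA) -> EvokedContrastResults:
    """Functional alias for ``EvokedContrastModel(summaries, alpha).fit()``."""
    return EvokedContrastModel(summaries, alpha).fit()
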