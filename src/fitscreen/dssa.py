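"""Differential strain sensitivity analysis (DSSA).

Infers per-gene growth effects from pooled deletion-strain barcode
arrays.  Each deletion strain carries a molecular barcode whose array
hybridisation signal tracks the strain's relative abundance in a
competitively grown pool.  Comparing treated against control pools
identifies strains whose deletion makes the cell sensitive (barcode
signal drops under treatment) or resistant (signal rises).

Pipeline
--------
1.  ``preprocess_arrays`` — winsorize saturated probes, log2-transform,
    subtract per-array robust background estimated from null features
    (probes matching no strain barcode).
2.  ``build_pairs`` — pair every treatment array with every control
    array of the same generation arm (3 replicates x 12 controls = 36
    pairs per condition).
3.  ``normalize_pair`` — remove the intensity-dependent trend of the
    log2 ratio (lowess on the MA plot).
4.  ``detect_outliers`` — per pair, call genes whose normalized log2
    ratio is an outlier under a robust-Gaussian null, with BH q-values
    (the "alpha-outlier" rule: calls controlled at level alpha).
5.  ``select_effective_pairs`` — drop pairs with abnormally high
    residual variance (Tukey fence).
6.  ``gene_binomial_calls`` — aggregate per-pair outlier calls per gene
    with an exact binomial tail test, BH-correct across genes.
7.  ``fitness_scores`` — mean log2 signal in exposed arrays minus mean
    in controls; negative = sensitive, positive = resistant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ArrayExperiment",
    "PairOutlierResult",
    "GeneCall",
    "preprocess_arrays",
    "build_pairs",
    "normalize_pair",
    "detect_outliers",
    "select_effective_pairs",
    "gene_binomial_calls",
    "fitness_scores",
    "summarize_conditions",
]

MAD_SCALE = 1.4826  # consistency factor: MAD -> sigma under normality


@dataclass
class ArrayExperiment:
    """Barcode-array intensities plus probe and array annotation.

    Parameters
    ----------
    intensities
        Non-negative signal, rows = probes, columns = array ids.
    probes
        DataFrame indexed like ``intensities`` rows with columns
        ``gene_id`` (empty/NaN for null features) and
        ``is_null_feature`` (bool).
    arrays
        DataFrame indexed by array id with columns ``dose_uM,
        generations, arm, replicate``; arm is ``treatment`` or
        ``control``; generations in {5, 15}.
    saturation_ceiling
        Signal value above which the scanner is considered saturated.
    """

    intensities: pd.DataFrame
    probes: pd.DataFrame
    arrays: pd.DataFrame
    saturation_ceiling: float

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("array intensities must be non-negative")
        if not self.probes.index.equals(self.intensities.index):
            raise ValueError("probe annotation index must match intensity rows")
        missing = set(self.intensities.columns) - set(self.arrays.index)
        if missing:
            raise ValueError(f"arrays missing from metadata: {sorted(missing)}")
        bad_arm = set(self.arrays["arm"]) - {"treatment", "control"}
        if bad_arm:
            raise ValueError(f"unknown arms: {sorted(bad_arm)}")
        if not self.probes["is_null_feature"].any():
            raise ValueError("experiment has no null-feature probes")

    @property
    def gene_probes(self) -> pd.Index:
        return self.probes.index[~self.probes["is_null_feature"]]

    @property
    def null_probes(self) -> pd.Index:
        return self.probes.index[self.probes["is_null_feature"]]

    def conditions(self) -> list[tuple]:
        """Distinct treatment (dose_uM, generations) combinations."""
        t = self.arrays[self.arrays["arm"] == "treatment"]
        return sorted(set(zip(t["dose_uM"], t["generations"])))


@dataclass
class AdjustedSignals:
    """Background-adjusted log2 signals from :func:`preprocess_arrays`."""

    log2: pd.DataFrame               # probes x arrays, background-subtracted
    background_scale: pd.Series      # per-array robust scale of null features
    saturated: pd.DataFrame          # bool, probes x arrays
    gene_map: pd.Series              # gene probe id -> gene id

    def gene_matrix(self) -> pd.DataFrame:
        """Adjusted log2 signals restricted to gene probes, indexed by gene."""
        m = self.log2.loc[self.gene_map.index]
        m.index = self.gene_map.to_numpy()
        return m


@dataclass
class PairOutlierResult:
    """Outlier analysis of one treatment-control array pair."""

    pair_id: str
    treatment: str
    control: str
    condition: tuple                 # (dose_uM, generations)
    genes: np.ndarray
    m_value: np.ndarray              # normalized log2 treatment/control
    q_value: np.ndarray
    sign: np.ndarray                 # sign of m - robust center
    residual_variance: float         # robust scale^2 of m-values
    effective: bool = True
    lowess_skipped: bool = False


@dataclass
class GeneCall:
    """Aggregated per-gene call for one condition."""

    gene: str
    condition: tuple
    k: int                  # successes: pairs significant with dominant sign
    m: int                  # effective pairs
    p: float                # exact binomial upper tail P(X >= k)
    q: float = np.nan
    fitness_score: float = np.nan
    label: str = "none"     # sensitive | resistant | none


def preprocess_arrays(exp: ArrayExperiment, pseudocount: float = 1.0) -> AdjustedSignals:
    """Winsorize, log2-transform, and background-adjust each array.

    Signals above the saturation ceiling are clipped to the ceiling and
    flagged.  After ``log2(signal + pseudocount)``, the median of the
    null-feature log2 signals is subtracted per array (robust location);
    their MAD x 1.4826 is retained as the per-array background scale.
    """
    x = self_check_nonzero(exp.intensities)
    saturated = x > exp.saturation_ceiling
    x = x.clip(upper=exp.saturation_ceiling)
    log2 = np.log2(x + pseudocount)

    nulls = log2.loc[exp.null_probes]
    if nulls.empty:
        raise ValueError("no null features available for background adjustment")
    loc = nulls.median(axis=0)
    scale = (nulls - loc).abs().median(axis=0) * MAD_SCALE
    adjusted = log2 - loc

    gene_map = exp.probes.loc[exp.gene_probes, "gene_id"]
    return AdjustedSignals(
        log2=adjusted,
        background_scale=scale,
        saturated=saturated,
        gene_map=gene_map,
    )


def self_check_nonzero(intensities: pd.DataFrame) -> pd.DataFrame:
    """Reject arrays that carry no signal at all."""
    dead = intensities.columns[(intensities == 0).all(axis=0)]
    if len(dead):
        raise ValueError(f"all-zero arrays: {list(dead)}")
    return intensities


def build_pairs(
    exp: ArrayExperiment, allow_arm_mismatch: bool = False
) -> list[tuple[str, str, tuple]]:
    """Cartesian treatment x control pairing within each generation arm.

    Returns ``(treatment_array, control_array, (dose_uM, generations))``
    triples.  With 3 treatment replicates and 12 controls per arm this
    yields the canonical 36 pairs per treatment condition.
    """
    meta = exp.arrays
    controls_by_gen = {
        g: list(sub.index)
        for g, sub in meta[meta["arm"] == "control"].groupby("generations")
    }
    pairs = []
    for t_id, row in meta[meta["arm"] == "treatment"].iterrows():
        gen = row["generations"]
        controls = controls_by_gen.get(gen, [])
        if not controls:
            if not allow_arm_mismatch:
                raise ValueError(
                    f"no control arrays for generation arm {gen!r} "
                    f"(treatment array {t_id!r})"
                )
            controls = list(itertools.chain.from_iterable(controls_by_gen.values()))
        for c_id in controls:
            pairs.append((t_id, c_id, (row["dose_uM"], gen)))
    return pairs


def normalize_pair(
    t_signal: pd.Series,
    c_signal: pd.Series,
    span: float = 0.4,
    iterations: int = 3,
    min_genes_for_lowess: int = 30,
) -> tuple[pd.Series, bool]:
    """Remove the intensity-dependent trend of a pair's log2 ratio.

    ``M = t - c`` (already in log2 space) and ``A = (t + c) / 2``; a
    lowess fit of M on A is subtracted so the trend is locally centered
    at zero.  With fewer than ``min_genes_for_lowess`` genes the global
    median is subtracted instead and the pair flagged.

    Returns ``(normalized M, lowess_skipped)``.
    """
    if not t_signal.index.equals(c_signal.index):
        raise ValueError("treatment and control arrays must share a gene set")
    m = t_signal - c_signal
    if m.size < min_genes_for_lowess:
        return m - m.median(), True
    a = (t_signal + c_signal) / 2.0
    trend = sm_lowess(
        m.to_numpy(), a.to_numpy(), frac=span, it=iterations,
        return_sorted=False,
    )
    return m - trend, False


def detect_outliers(
    m_values: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Alpha-outlier calls for one pair's normalized log2 ratios.

    The bulk of strains is assumed unaffected, so the null is a robust
    Gaussian fit (median / MAD x 1.4826) to the m-values.  Two-sided
    normal p-values are BH-corrected across genes; a gene is an outlier
    when its q-value is at most ``alpha``.  A degenerate zero scale
    yields no calls (all q = 1).
    """
    m = m_values.to_numpy(dtype=float)
    center = float(np.median(m))
    scale = float(np.median(np.abs(m - center)) * MAD_SCALE)
    resid = m - center
    if scale == 0:
        q = np.ones(m.size)
        p = np.ones(m.size)
    else:
        z = resid / scale
        p = 2.0 * stats.norm.sf(np.abs(z))
        q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "m_value": m_values,
            "p_value": p,
            "q_value": q,
            "sign": np.sign(resid).astype(int),
            "outlier": (q <= alpha) & (scale > 0),
        },
        index=m_values.index,
    )


def analyze_pairs(
    adjusted: AdjustedSignals,
    exp: ArrayExperiment,
    span: float = 0.4,
    alpha: float = 0.05,
) -> list[PairOutlierResult]:
    """Run normalization + outlier detection over every built pair."""
    genes = adjusted.gene_matrix()
    results = []
    for t_id, c_id, cond in build_pairs(exp):
        m, skipped = normalize_pair(genes[t_id], genes[c_id], span=span)
        out = detect_outliers(m, alpha=alpha)
        center = float(np.median(m))
        scale = float(np.median(np.abs(m - center)) * MAD_SCALE)
        results.append(
            PairOutlierResult(
                pair_id=f"{t_id}|{c_id}",
                treatment=t_id,
                control=c_id,
                condition=cond,
                genes=m.index.to_numpy(),
                m_value=out["m_value"].to_numpy(),
                q_value=out["q_value"].to_numpy(),
                sign=out["sign"].to_numpy(),
                residual_variance=scale ** 2,
                lowess_skipped=skipped,
            )
        )
    return results


def select_effective_pairs(
    pairs: list[PairOutlierResult],
) -> tuple[list[PairOutlierResult], pd.DataFrame]:
    """Flag pairs with abnormally high residual variance as non-effective.

    Within each condition group the Tukey upper fence
    ``Q3 + 1.5 * IQR`` over the pairs' residual variances is applied —
    the programmatic analogue of screening per-pair box plots.  A report
    with the fence, each pair's variance and the lag-1 autocorrelation
    of per-pair scale across pair order (a serial-correlation
    diagnostic, never auto-excluding) is returned alongside.
    """
    report_rows = []
    by_cond: dict = {}
    for pr in pairs:
        by_cond.setdefault(pr.condition, []).append(pr)
    for cond, group in by_cond.items():
        if len(group) < 4:
            for pr in group:
                pr.effective = True
                report_rows.append(_pair_report_row(pr, np.nan, np.nan))
            continue
        var = np.array([pr.residual_variance for pr in group])
        q1, q3 = np.percentile(var, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        scales = np.sqrt(var)
        if scales.size > 2 and scales.std() > 0:
            lag1 = float(np.corrcoef(scales[:-1], scales[1:])[0, 1])
        else:
            lag1 = np.nan
        for pr in group:
            pr.effective = pr.residual_variance <= fence
            report_rows.append(_pair_report_row(pr, fence, lag1))
        if not any(pr.effective for pr in group):
            raise ValueError(
                f"all pairs excluded for condition {cond}; manual review required"
            )
    report = pd.DataFrame(report_rows)
    return [pr for pr in pairs if pr.effective], report


def _pair_report_row(pr: PairOutlierResult, fence: float, lag1: float) -> dict:
    return {
        "pair_id": pr.pair_id,
        "condition": str(pr.condition),
        "residual_variance": pr.residual_variance,
        "variance_fence": fence,
        "scale_lag1_autocorr": lag1,
        "effective": pr.effective,
    }


def binomial_tail(k: int, m: int, pi0: float) -> float:
    """Exact upper binomial tail P(X >= k) for X ~ Binomial(m, pi0)."""
    if not 0 <= k <= m:
        raise ValueError("k must lie in [0, m]")
    return float(stats.binom.sf(k - 1, m, pi0))


def gene_binomial_calls(
    pairs: list[PairOutlierResult],
    pi0: float = 0.05,
    alpha_q: float = 0.05,
    alpha_pair: float = 0.05,
    strict: bool = True,
) -> pd.DataFrame:
    """Aggregate per-pair outlier calls into per-gene condition calls.

    For each gene the dominant sign is the strict-majority sign of its
    m-values over the condition's effective pairs (exact tie: no call).
    A pair counts as a success when the gene is an outlier there
    (q <= ``alpha_pair``) with the dominant sign.  The raw p-value is
    the exact binomial upper tail P(X >= k | m pairs, ``pi0``), with
    ``pi0`` the per-pair success probability under the null (default:
    the per-pair call level).  q-values are BH over genes within each
    condition; a gene is called when q <= ``alpha_q`` — and, in strict
    mode, only when it succeeded in every effective pair (k = m).

    Returns a tidy frame ``gene, condition, k, m, p, q, called, sign``.
    """
    if not 0 < pi0 < 1:
        raise ValueError("pi0 must be in (0, 1)")
    eff = [pr for pr in pairs if pr.effective]
    if not eff:
        raise ValueError("no effective pairs to aggregate")
    rows = []
    by_cond: dict = {}
    for pr in eff:
        by_cond.setdefault(pr.condition, []).append(pr)
    for cond, group in sorted(by_cond.items(), key=lambda kv: str(kv[0])):
        genes = group[0].genes
        signs = np.stack([pr.sign for pr in group])          # pairs x genes
        outlier = np.stack([pr.q_value <= alpha_pair for pr in group])
        m = len(group)
        net = signs.sum(axis=0)
        dominant = np.sign(net).astype(int)                  # 0 on exact tie
        success = (outlier & (signs == dominant[None, :]) & (dominant != 0)).sum(axis=0)
        p = stats.binom.sf(success - 1, m, pi0)
        q = multipletests(p, method="fdr_bh")[1]
        called = q <= alpha_q
        if strict:
            called &= success == m
        called &= dominant != 0
        for g, kk, pp, qq, cc, dd in zip(genes, success, p, q, called, dominant):
            rows.append(
                {
                    "gene": g,
                    "condition": cond,
                    "k": int(kk),
                    "m": m,
                    "p": float(pp),
                    "q": float(qq),
                    "called": bool(cc),
                    "sign": int(dd),
                }
            )
    return pd.DataFrame(rows)


def fitness_scores(
    adjusted: AdjustedSignals, exp: ArrayExperiment, condition: tuple
) -> pd.Series:
    """Mean adjusted log2 signal, exposed minus control, per gene.

    ``condition`` is a ``(dose_uM, generations)`` pair selecting the
    exposed arrays; controls are the same generation arm's control
    arrays.  Negative scores mean the deletion strain grew worse under
    exposure (gene required for tolerance — "sensitive"); positive
    scores mean resistance.
    """
    dose, gen = condition
    meta = exp.arrays
    exposed = meta[
        (meta["arm"] == "treatment")
        & (meta["dose_uM"] == dose)
        & (meta["generations"] == gen)
    ].index
    control = meta[(meta["arm"] == "control") & (meta["generations"] == gen)].index
    if len(exposed) == 0 or len(control) == 0:
        raise ValueError(f"condition {condition} lacks exposed or control arrays")
    genes = adjusted.gene_matrix()
    return genes[list(exposed)].mean(axis=1) - genes[list(control)].mean(axis=1)


def attach_scores_and_labels(
    calls: pd.DataFrame, scores_by_condition: dict
) -> pd.DataFrame:
    """Join fitness scores onto binomial calls and assign labels.

    Called genes are labelled by the sign of their fitness score
    (negative = sensitive, positive = resistant); uncalled genes and
    exact-zero scores get ``none``.
    """
    out = calls.copy()
    out["fitness_score"] = [
        float(scores_by_condition[cond].get(g, np.nan))
        for g, cond in zip(out["gene"], out["condition"])
    ]
    label = np.where(
        out["called"] & (out["fitness_score"] < 0),
        "sensitive",
        np.where(out["called"] & (out["fitness_score"] > 0), "resistant", "none"),
    )
    out["label"] = label
    return out


def summarize_conditions(calls: pd.DataFrame, min_conditions: int = 3) -> dict:
    """Cross-condition summary of sensitive/resistant calls.

    Returns per-condition counts, the union of called genes over all
    conditions, genes called in at least ``min_conditions`` conditions,
    and pairwise overlap counts between conditions — the tabular
    analogues of the screen's per-condition bar chart and Venn overlap
    figures.
    """
    called = calls[calls["label"] != "none"]
    per_condition = (
        called.groupby(["condition", "label"]).size().unstack(fill_value=0)
        if len(called)
        else pd.DataFrame()
    )
    union: dict = {"sensitive": set(), "resistant": set()}
    membership: dict = {}
    for _, row in called.iterrows():
        union[row["label"]].add(row["gene"])
        membership.setdefault((row["gene"], row["label"]), set()).add(row["condition"])
    recurrent = {
        lab: sorted(
            g for (g, l), conds in membership.items()
            if l == lab and len(conds) >= min_conditions
        )
        for lab in ("sensitive", "resistant")
    }
    conditions = sorted(set(calls["condition"]), key=str)
    overlap = pd.DataFrame(0, index=range(len(conditions)), columns=range(len(conditions)))
    sets = {
        c: set(called[called["condition"] == c]["gene"]) for c in conditions
    }
    for i, ci in enumerate(conditions):
        for j, cj in enumerate(conditions):
            overlap.iloc[i, j] = len(sets[ci] & sets[cj])
    overlap.index = [str(c) for c in conditions]
    overlap.columns = [str(c) for c in conditions]
    return {
        "per_condition": per_condition,
        "union_counts": {lab: len(s) for lab, s in union.items()},
        "union_sets": {lab: sorted(s) for lab, s in union.items()},
        "recurrent": recurrent,
        "overlap": overlap,
    }


def run_dssa(
    exp: ArrayExperiment,
    span: float = 0.4,
    alpha_pair: float = 0.05,
    pi0: float = 0.05,
    alpha_q: float = 0.05,
    strict: bool = True,
) -> dict:
    """Full DSSA pipeline on one experiment; returns calls + reports."""
    adjusted = preprocess_arrays(exp)
    pairs = analyze_pairs(adjusted, exp, span=span, alpha=alpha_pair)
    effective, pair_report = select_effective_pairs(pairs)
    calls = gene_binomial_calls(
        effective, pi0=pi0, alpha_q=alpha_q, alpha_pair=alpha_pair, strict=strict
    )
    scores = {cond: fitness_scores(adjusted, exp, cond) for cond in exp.conditions()}
    calls = attach_scores_and_labels(calls, scores)
    return {
        "adjusted": adjusted,
        "pairs": pairs,
        "pair_report": pair_report,
        "calls": calls,
        "scores": scores,
    }
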