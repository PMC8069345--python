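"""Expression filter cascade for tumor-suppressor-gene candidates.

Hypermethylated, EPIC-confirmed genes are funnelled through three stages:

1. regeneration: expression drops more than ``fc_threshold``-fold four hours
   after partial hepatectomy relative to sham surgery AND recovers by one
   week (within ``recovery_factor``-fold of the sham level);
2. tumor cohort: median expression in tumors is more than
   ``fc_threshold``-fold below normal tissue, with a two-sided Mann-Whitney
   rank test (normal approximation, tie-corrected) significant at ``alpha``
   on the raw p-value (Benjamini-Hochberg q-values are reported alongside);
3. exclusion of already-known tumor suppressor genes.

Fold changes use a pseudocount to guard zero denominators. Gene symbols are
upper-cased throughout so mouse regeneration symbols match human ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .integration import normalize_set, normalize_symbol

DEFAULT_FC_THRESHOLD = 2.0
DEFAULT_RECOVERY_FACTOR = 2.0
DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_ALPHA = 1e-4
KNOWN_TSGS = frozenset({"AJAP1", "GATA5", "LRAT"})

STATUS_CANDIDATE = "candidate"


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    if len(p) == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def regeneration_filter(
    expr: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    recovery_factor: float = DEFAULT_RECOVERY_FACTOR,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene regeneration-downregulation result.

    ``expr`` is long (gene, condition, value) with conditions sham, ph4h,
    ph1wk. fold_down = (sham + pc) / (ph4h + pc); recovered iff
    ph1wk >= sham / recovery_factor; passes iff fold_down > fc_threshold
    (strict) and recovered. Genes missing a condition are skipped with a
    warning.
    """
    df = expr.copy()
    df["gene"] = df["gene"].map(normalize_symbol)
    wide = df.pivot_table(index="gene", columns="condition", values="value", aggfunc="mean")
    needed = {"sham", "ph4h", "ph1wk"}
    missing = needed - set(wide.columns)
    if missing:
        raise ValueError(f"expression table lacks condition(s): {sorted(missing)}")
    incomplete = wide[["sham", "ph4h", "ph1wk"]].isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"{int(incomplete.sum())} gene(s) missing a condition; skipped", stacklevel=2
        )
        wide = wide[~incomplete]
    out = pd.DataFrame(
        {
            "gene": wide.index,
            "sham": wide["sham"].to_numpy(),
            "ph4h": wide["ph4h"].to_numpy(),
            "ph1wk": wide["ph1wk"].to_numpy(),
        }
    )
    out["fold_down"] = (out["sham"] + pseudocount) / (out["ph4h"] + pseudocount)
    out["recovered"] = out["ph1wk"] >= out["sham"] / recovery_factor
    out["passes"] = (out["fold_down"] > fc_threshold) & out["recovered"]
    return out.reset_index(drop=True)


def tumor_filter(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    use_q: bool = False,
) -> pd.DataFrame:
    """Per-gene tumor-downregulation result on genes x samples matrices.

    fold_down = (normal median + pc) / (tumor median + pc); p from a
    two-sided Mann-Whitney test (asymptotic, tie-corrected; p = 1 by
    convention for a gene constant across all samples); q = BH-adjusted.
    passes iff fold_down > fc_threshold and (q if use_q else p) < alpha.
    """
    if tumor.shape[1] < 3 or normal.shape[1] < 3:
        raise ValueError("need at least 3 samples per group")
    tumor = tumor.copy()
    tumor.index = [normalize_symbol(g) for g in tumor.index]
    normal = normal.copy()
    normal.index = [normalize_symbol(g) for g in normal.index]
    common = [g for g in tumor.index if g in set(normal.index)]
    rows = []
    for g in common:
        tv = np.asarray(tumor.loc[g], float)
        nv = np.asarray(normal.loc[g], float)
        med_t, med_n = float(np.median(tv)), float(np.median(nv))
        if np.all(np.concatenate([tv, nv]) == tv[0]):
            p = 1.0
        else:
            p = float(
                stats.mannwhitneyu(nv, tv, alternative="two-sided", method="asymptotic").pvalue
            )
        rows.append((g, med_n, med_t, (med_n + pseudocount) / (med_t + pseudocount), p))
    out = pd.DataFrame(
        rows, columns=["gene", "normal_median", "tumor_median", "fold_down", "p_value"]
    )
    out["q_value"] = _bh_qvalues(out["p_value"].to_numpy())
    crit = out["q_value"] if use_q else out["p_value"]
    out["passes"] = (out["fold_down"] > fc_threshold) & (crit < alpha)
    return out


def exclude_known(genes, known_tsgs=KNOWN_TSGS) -> pd.DataFrame:
    """Candidate table from the tumor-pass gene list: known tumor suppressors
    are marked excluded, the remainder are candidates."""
    known = normalize_set(known_tsgs)
    rows = []
    for g in sorted(normalize_set(genes)):
        is_known = g in known
        rows.append(
            {
                "gene": g,
                "known_tsg": is_known,
                "status": "excluded(known_tsg)" if is_known else STATUS_CANDIDATE,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "known_tsg", "status"])


@dataclass
class CascadeResult:
    table: pd.DataFrame
    funnel: dict[str, int] = field(default_factory=dict)
    regeneration: pd.DataFrame | None = None
    tumor: pd.DataFrame | None = None

    @property
    def candidates(self) -> set[str]:
        t = self.table
        return set(t.loc[t["status"] == STATUS_CANDIDATE, "gene"])


def run_cascade(
    confirmed_genes,
    regeneration_expr: pd.DataFrame,
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    recovery_factor: float = DEFAULT_RECOVERY_FACTOR,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    alpha: float = DEFAULT_ALPHA,
    use_q: bool = False,
    known_tsgs=KNOWN_TSGS,
) -> CascadeResult:
    """Run the full funnel on the confirmed hypermethylated gene set.

    Stage counts are reported in pipeline order (confirmed ->
    regeneration-pass -> tumor-pass -> candidates) and are non-increasing by
    construction. The tumor test is run only on regeneration-pass genes.
    """
    confirmed = normalize_set(confirmed_genes)
    regen = regeneration_filter(regeneration_expr, fc_threshold, recovery_factor, pseudocount)
    regen = regen[regen["gene"].isin(confirmed)]
    unmatched = confirmed - set(regen["gene"])
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} confirmed gene(s) absent from the regeneration table",
            stacklevel=2,
        )
    regen_pass = set(regen.loc[regen["passes"], "gene"])

    tmask = [normalize_symbol(g) in regen_pass for g in tumor.index]
    nmask = [normalize_symbol(g) in regen_pass for g in normal.index]
    if regen_pass and any(tmask) and any(nmask):
        tumor_res = tumor_filter(
            tumor.loc[tmask], normal.loc[nmask], fc_threshold, alpha, pseudocount, use_q
        )
    else:
        tumor_res = pd.DataFrame(
            columns=["gene", "normal_median", "tumor_median", "fold_down", "p_value", "q_value", "passes"]
        )
    tumor_pass = set(tumor_res.loc[tumor_res["passes"], "gene"]) if len(tumor_res) else set()

    known = normalize_set(known_tsgs)
    rows = []
    for g in sorted(confirmed):
        r_pass = g in regen_pass
        t_pass = g in tumor_pass
        is_known = g in known
        if not r_pass:
            status = "excluded(regeneration)"
        elif not t_pass:
            status = "excluded(tumor)"
        elif is_known:
            status = "excluded(known_tsg)"
        else:
            status = STATUS_CANDIDATE
        rows.append(
            {
                "gene": g,
                "hypermethylated_confirmed": True,
                "regeneration_pass": r_pass,
                "tumor_pass": t_pass,
                "known_tsg": is_known,
                "status": status,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "hypermethylated_confirmed",
            "regeneration_pass",
            "tumor_pass",
            "known_tsg",
            "status",
        ],
    )
    funnel = {
        "confirmed": len(confirmed),
        "regeneration_pass": len(regen_pass),
        "tumor_pass": len(tumor_pass & regen_pass),
        "candidates": int((table["status"] == STATUS_CANDIDATE).sum()),
    }
    return CascadeResult(table, funnel, regen, tumor_res)
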