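"""End-to-end synthetic study orchestration.

:func:`run_study` simulates a cohort, scores the questionnaires, validates
the resilience scale, generates and phenotypes accelerometer traces for an
actigraphy subset, runs the univariate comparisons (classical p, bootstrap
CI, permutation p) and the multivariate stages (forest importance,
moderator regression, beta regression), and assembles everything into a
:class:`StudyReport` that serialises to JSON and a human-readable text
table.  Every stage draws its randomness from a seed spawned from the
study seed, so identical seeds give byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .actigraphy import ActivityConfig, summarize
from .models import ForestConfig, beta_regression, forest_importance, moderator_regression
from .scales import WORRY_ITEMS, score_cohort
from .scaleval import OrdinalItemMatrix, ValidationConfig, internal_consistency, prune_items
from .stats import (
    TestResult,
    chi_square_trend,
    fisher_exact_2x2,
    spearman,
    two_sample_t,
    wilcoxon_rank_sum,
)
from .synthdata import CohortConfig, generate_cohort, generate_trace, write_cohort

__all__ = ["StudyReport", "run_study"]

_P_FLOOR = 1e-4


@dataclass
class StudyReport:
    provenance: dict
    cohort_summary: dict
    worry_table: dict
    resilience_table: dict
    scale_validation: dict | None
    activity_comparison: dict | None
    importance: dict | None
    moderation: dict | None
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1, default=_jsonify)

    def to_text(self) -> str:
        lines = [
            f"actipain study report (seed {self.provenance['seed']}, "
            f"config {self.provenance['config_hash'][:12]})",
            "",
            "== cohort comparisons ==",
        ]
        for name, entry in {**self.cohort_summary, **self.worry_table,
                            **self.resilience_table}.items():
            lines.append(f"  {name}: {entry.get('display', '')} p={_fmt_p(entry['p'])}")
        if self.activity_comparison:
            lines.append("== activity (CP vs NoCP) ==")
            for name, entry in self.activity_comparison.items():
                lines.append(
                    f"  {name}: p={_fmt_p(entry['p'])} "
                    f"perm p={_fmt_p(entry.get('p_permuted'))}"
                )
        if self.scale_validation:
            sv = self.scale_validation
            lines.append(
                f"== scale validation == factors={sv['n_factors']} "
                f"retained={len(sv['retained_items'])} removed={sv['removed_items']} "
                f"alpha={sv['alpha_raw']:.2f} ordinal alpha={sv['alpha_ordinal']:.2f}"
            )
        if self.importance:
            lines.append(
                "== forest == consistently informative: "
                + (", ".join(sorted(self.importance["consistently_informative"])) or "(none)")
            )
        if self.moderation:
            for name, entry in self.moderation.items():
                lines.append(
                    f"== {name} == r2={entry['r_squared']:.2f} "
                    f"interaction p={_fmt_p(entry['interaction_p'])}"
                )
        if self.warnings:
            lines.append("== warnings ==")
            lines.extend(f"  {w}" for w in self.warnings)
        return "\n".join(lines) + "\n"


def _fmt_p(p) -> str:
    if p is None:
        return "NA"
    return f"<{_P_FLOOR:g}" if p < _P_FLOOR else f"{p:.2f}"


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _tr_entry(res: TestResult, display: str = "") -> dict:
    d = {
        "statistic": res.statistic,
        "p": res.p_original,
        "p_permuted": res.p_permuted,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "method": res.method,
    }
    if display:
        d["display"] = display
    return d


def run_study(
    cohort_config: CohortConfig | None = None,
    activity_config: ActivityConfig | None = None,
    forest_config: ForestConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    n_boot: int = 1000,
    n_perm: int = 1000,
    actigraphy_subset: int = 68,
    wear_days: int = 14,
    include_scaleval: bool = True,
    include_actigraphy: bool = True,
    include_multivariate: bool = True,
    n_parallel_datasets: int = 60,
) -> StudyReport:
    """Run the full synthetic study.  Deterministic given ``seed``."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(8)]
    cohort_config = replace(cohort_config or CohortConfig(), seed=seeds[0])
    activity_config = activity_config or ActivityConfig()
    warnings_log: list[str] = []

    cohort, truths, devices = generate_cohort(cohort_config)
    scored = score_cohort(cohort)
    cp = scored[scored.group == "CP"]
    nocp = scored[scored.group == "NoCP"]

    # ---- univariate cohort comparisons -----------------------------------
    rs_kwargs = dict(n_boot=n_boot, n_perm=n_perm)
    cohort_summary = {
        "age_t": _tr_entry(
            two_sample_t(cp.age, nocp.age, seed=seeds[1], **rs_kwargs),
            display=f"{cp.age.mean():.0f} ({cp.age.std():.0f}) vs "
            f"{nocp.age.mean():.0f} ({nocp.age.std():.0f})",
        ),
        "female_fisher": _tr_entry(
            fisher_exact_2x2(
                [
                    [int(cp.female.sum()), int((1 - cp.female).sum())],
                    [int(nocp.female.sum()), int((1 - nocp.female).sum())],
                ]
            )
        ),
        "education_trend": _tr_entry(
            chi_square_trend(
                [
                    np.bincount(cp.education, minlength=4).tolist(),
                    np.bincount(nocp.education, minlength=4).tolist(),
                ]
            )
        ),
        "employment_trend": _tr_entry(
            chi_square_trend(
                [
                    np.bincount(cp.employment, minlength=3).tolist(),
                    np.bincount(nocp.employment, minlength=3).tolist(),
                ]
            )
        ),
        "eq5d_vas_wilcoxon": _tr_entry(
            wilcoxon_rank_sum(cp.eq5d_vas, nocp.eq5d_vas, seed=seeds[1], **rs_kwargs)
        ),
        "resilience_vs_vas_spearman": _tr_entry(
            spearman(scored.rs_score, scored.eq5d_vas, n_boot=n_boot, seed=seeds[1])
        ),
    }
    worry_table = {
        f"worry_{item}_trend": _tr_entry(
            chi_square_trend(
                [
                    np.bincount(cp[f"worry_{item}"], minlength=5).tolist(),
                    np.bincount(nocp[f"worry_{item}"], minlength=5).tolist(),
                ]
            )
        )
        for item in WORRY_ITEMS
    }
    resilience_table = {}
    for col, label in (("rs_score", "rs"), ("cdrisc_score", "cdrisc")):
        resilience_table[f"{label}_full_t"] = _tr_entry(
            two_sample_t(cp[col], nocp[col], seed=seeds[2], **rs_kwargs),
            display=f"{cp[col].mean():.0f} ({cp[col].std():.0f}) vs "
            f"{nocp[col].mean():.0f} ({nocp[col].std():.0f})",
        )
        for lang in ("english", "isizulu"):
            a = cp.loc[cp.language == lang, col]
            b = nocp.loc[nocp.language == lang, col]
            if len(a) >= 2 and len(b) >= 2:
                resilience_table[f"{label}_{lang}_t"] = _tr_entry(
                    two_sample_t(a, b, seed=seeds[2], **rs_kwargs)
                )

    # ---- resilience-scale validation (isiZulu RS completers) -------------
    scale_validation = None
    if include_scaleval:
        zulu = cohort[cohort.language == "isizulu"]
        items = OrdinalItemMatrix(
            zulu[[f"rs_item_{j + 1}" for j in range(23)]].astype(int)
        )
        vcfg = ValidationConfig(n_parallel_datasets=n_parallel_datasets, seed=seeds[3])
        sol = prune_items(items, vcfg)
        alpha_raw, alpha_ord = internal_consistency(items)
        scale_validation = {
            "n_factors": sol.n_factors,
            "retained_items": sol.retained_items,
            "removed_items": sol.removed_items,
            "alpha_raw": alpha_raw,
            "alpha_ordinal": alpha_ord,
        }

    # ---- actigraphy subset ------------------------------------------------
    activity_comparison = None
    summaries = None
    if include_actigraphy:
        n_sub = min(actigraphy_subset, len(truths))
        by_group = {"CP": [], "NoCP": []}
        for t in truths:
            by_group[t.group].append(t)
        half = (n_sub + 1) // 2
        subset = by_group["CP"][:half] + by_group["NoCP"][: n_sub - min(half, len(by_group["CP"]))]
        trace_seeds = np.random.SeedSequence(seeds[4]).spawn(len(subset))
        rows = []
        for t, s in zip(subset, trace_seeds):
            series = generate_trace(t, devices[t.device_id], days=wear_days, seed=s)
            try:
                summ = summarize(series, activity_config)
            except ValueError as err:  # inconsistent wearer: excluded
                warnings_log.append(f"actigraphy: excluded {t.participant_id}: {err}")
                continue
            row = summ.to_dict()
            row["group"] = t.group
            rows.append(row)
        summaries = pd.DataFrame(rows)
        a = summaries[summaries.group == "CP"]
        b = summaries[summaries.group == "NoCP"]
        activity_comparison = {
            "time_active_wilcoxon": _tr_entry(
                wilcoxon_rank_sum(
                    a.minutes_active_per_day, b.minutes_active_per_day,
                    seed=seeds[5], **rs_kwargs,
                )
            ),
            "intensity_wilcoxon": _tr_entry(
                wilcoxon_rank_sum(
                    a.median_active_intensity.dropna(),
                    b.median_active_intensity.dropna(),
                    seed=seeds[5], **rs_kwargs,
                )
            ),
        }
        for bin_name in ("zero", "1_24", "25_49", "50_74", "75_plus"):
            col = f"endurance_{bin_name}"
            activity_comparison[f"{col}_wilcoxon"] = _tr_entry(
                wilcoxon_rank_sum(a[col], b[col], seed=seeds[5], **rs_kwargs)
            )

    # ---- multivariate -----------------------------------------------------
    importance = moderation = None
    if include_multivariate and summaries is not None and len(summaries) >= 20:
        merged = summaries.merge(scored, on="participant_id", suffixes=("", "_q"))
        predictors = merged[
            ["age", "female", "education", "employment", "bmi", "rs_score"]
            + [f"worry_{w}" for w in WORRY_ITEMS]
        ].copy()
        predictors["pain_group"] = (merged.group == "CP").astype(int)
        fcfg = forest_config or ForestConfig(seed=seeds[6])
        imp = forest_importance(predictors, merged.minutes_active_per_day, fcfg)
        importance = {
            "variables": imp.variables,
            "importances": {k: v.tolist() for k, v in imp.importances.items()},
            "thresholds": imp.thresholds,
            "informative": {k: sorted(v) for k, v in imp.informative.items()},
            "consistently_informative": sorted(imp.consistently_informative),
        }
        mod_act = moderator_regression(
            merged.minutes_active_per_day,
            (merged.group == "CP").astype(float),
            merged.rs_score,
        )
        xc = (scored.group == "CP").astype(float)
        xc = xc - xc.mean()
        mc = scored.rs_score - scored.rs_score.mean()
        qol = beta_regression(
            scored.eq5d_vas / 100.0,
            pd.DataFrame({"pain": xc, "resilience": mc, "pain:resilience": xc * mc}),
        )
        moderation = {
            "pain_activity_moderation": {
                "r_squared": mod_act.r_squared,
                "interaction_p": mod_act.interaction_p,
                "simple_slopes": mod_act.simple_slopes.to_dict(orient="records"),
            },
            "pain_qol_beta": {
                "r_squared": qol.r_squared,
                "interaction_p": float(qol.pvalues["pain:resilience"]),
                "phi": qol.phi,
                "coefficients": qol.params.to_dict(),
            },
        }

    config_blob = json.dumps(
        {
            "cohort": asdict(cohort_config),
            "activity": asdict(activity_config),
            "n_boot": n_boot,
            "n_perm": n_perm,
            "actigraphy_subset": actigraphy_subset,
            "wear_days": wear_days,
        },
        sort_keys=True,
        default=_jsonify,
    )
    report = StudyReport(
        provenance={
            "seed": seed,
            "stage_seeds": seeds,
            "config_hash": hashlib.sha256(config_blob.encode()).hexdigest(),
            "version": __version__,
        },
        cohort_summary=cohort_summary,
        worry_table=worry_table,
        resilience_table=resilience_table,
        scale_validation=scale_validation,
        activity_comparison=activity_comparison,
        importance=importance,
        moderation=moderation,
        warnings=warnings_log,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, devices, outdir)
        scored.to_csv(outdir / "scored.csv", index=False)
        if summaries is not None:
            summaries.to_csv(outdir / "activity_summaries.csv", index=False)
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "report.txt").write_text(report.to_text())
    return report
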