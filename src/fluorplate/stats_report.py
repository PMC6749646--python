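"""Genotype/treatment comparison and run reporting.

Comparisons follow standard phenotyping practice: Shapiro–Wilk normality
and Levene homogeneity checks are reported alongside (never used to
silently switch tests), two groups are compared with a two-sample t test,
more with one-way ANOVA plus Tukey–Kramer HSD, and a Kruskal–Wallis
fallback is available by flag.  Pairwise outcomes are condensed into a
compact letter display.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = ["ComparisonResult", "compare_groups", "compact_letter_display",
           "build_report"]


@dataclass
class ComparisonResult:
    """Full outcome of a single-parameter group comparison."""

    parameter: str
    group_column: str
    groups: pd.DataFrame          # group, n, mean, se
    test_name: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame        # group1, group2, p_adj, reject
    letters: dict[str, str]
    normality_p: dict[str, float]  # Shapiro–Wilk per group (NaN if n < 3)
    levene_p: float
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        """One tidy row per group for CSV export."""
        rows = []
        for _, g in self.groups.iterrows():
            rows.append({
                "parameter": self.parameter,
                "group": g["group"],
                "n": g["n"],
                "mean": g["mean"],
                "se": g["se"],
                "letter": self.letters[str(g["group"])],
                "test": self.test_name,
                "statistic": self.statistic,
                "p_value": self.p_value,
                "shapiro_p": self.normality_p[str(g["group"])],
                "levene_p": self.levene_p,
            })
        return pd.DataFrame(rows)


def compact_letter_display(
    group_names: list[str], pairwise: pd.DataFrame, means: dict[str, float]
) -> dict[str, str]:
    """Assign significance letters from pairwise rejections.

    Uses the insert-and-absorb algorithm: start from one class holding
    all groups, split it for every rejected pair, drop classes that are
    subsets of others, then letter the classes in order of decreasing
    class mean.  Groups not significantly different share at least one
    letter; significantly different groups share none.
    """
    classes: list[set[str]] = [set(group_names)]
    for _, row in pairwise.iterrows():
        if not row["reject"]:
            continue
        g1, g2 = str(row["group1"]), str(row["group2"])
        new_classes = []
        for cls in classes:
            if g1 in cls and g2 in cls:
                new_classes.extend([cls - {g1}, cls - {g2}])
            else:
                new_classes.append(cls)
        # absorb: dedupe, then drop classes strictly contained in another
        unique: list[set[str]] = []
        for c in new_classes:
            if c and c not in unique:
                unique.append(c)
        classes = [c for c in unique if not any(c < d for d in unique)]
    classes.sort(key=lambda c: -max(means[g] for g in c))
    letters = {g: "" for g in group_names}
    for letter, cls in zip("abcdefghijklmnopqrstuvwxyz", classes):
        for g in cls:
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def compare_groups(
    table: pd.DataFrame,
    parameter: str,
    group_column: str,
    alpha: float = 0.05,
    method: str = "parametric",
) -> ComparisonResult:
    """Compare a parameter across groups.

    ``method="parametric"`` (default) runs a t test (2 groups) or one-way
    ANOVA + Tukey–Kramer HSD (> 2); ``method="kruskal"`` substitutes a
    Kruskal–Wallis test with pairwise Mann–Whitney U tests
    (Benjamini–Hochberg adjusted).  Assumption checks (Shapiro–Wilk per
    group, Levene across groups) are always reported, never gating.
    """
    data = table[[group_column, parameter]].dropna()
    grouped = {str(name): sub[parameter].to_numpy(dtype=float)
               for name, sub in data.groupby(group_column)}
    if len(grouped) < 2:
        raise ValueError(f"need >= 2 groups in {group_column!r}, got {len(grouped)}")
    for name, vals in grouped.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has n={len(vals)} < 2")
    names = sorted(grouped)
    arrays = [grouped[n] for n in names]

    normality_p = {}
    for name, vals in grouped.items():
        if len(vals) >= 3 and np.ptp(vals) > 0:
            normality_p[name] = float(stats.shapiro(vals).pvalue)
        else:
            normality_p[name] = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        levene_p = float(stats.levene(*arrays, center="median").pvalue)

    if method == "parametric":
        if len(names) == 2:
            test_name = "t-test"
            res = stats.ttest_ind(*arrays)
            stat, p = float(res.statistic), float(res.pvalue)
            pairwise = pd.DataFrame([{
                "group1": names[0], "group2": names[1],
                "p_adj": p, "reject": p < alpha,
            }])
        else:
            test_name = "one-way ANOVA + Tukey-Kramer HSD"
            res = stats.f_oneway(*arrays)
            stat, p = float(res.statistic), float(res.pvalue)
            tukey = pairwise_tukeyhsd(
                data[parameter].to_numpy(dtype=float),
                data[group_column].astype(str).to_numpy(),
                alpha=alpha,
            )
            tk = pd.DataFrame(
                tukey.summary().data[1:], columns=tukey.summary().data[0]
            )
            pairwise = pd.DataFrame({
                "group1": tk["group1"].astype(str),
                "group2": tk["group2"].astype(str),
                "p_adj": tk["p-adj"].astype(float),
                "reject": tk["reject"].astype(bool),
            })
    elif method == "kruskal":
        test_name = "Kruskal-Wallis"
        res = stats.kruskal(*arrays)
        stat, p = float(res.statistic), float(res.pvalue)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        raw = [float(stats.mannwhitneyu(grouped[a], grouped[b]).pvalue)
               for a, b in pairs]
        reject, p_adj, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
        pairwise = pd.DataFrame({
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "p_adj": p_adj,
            "reject": reject,
        })
    else:
        raise ValueError(f"unknown method {method!r}")

    summary = pd.DataFrame({
        "group": names,
        "n": [len(grouped[n]) for n in names],
        "mean": [float(np.mean(grouped[n])) for n in names],
        "se": [float(np.std(grouped[n], ddof=1) / np.sqrt(len(grouped[n])))
               for n in names],
    })
    means = dict(zip(summary["group"], summary["mean"]))
    letters = compact_letter_display(names, pairwise, means)
    return ComparisonResult(
        parameter=parameter, group_column=group_column, groups=summary,
        test_name=test_name, statistic=stat, p_value=p, pairwise=pairwise,
        letters=letters, normality_p=normality_p, levene_p=levene_p, alpha=alpha,
    )


def _sha256_of_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def _versions() -> dict[str, str]:
    import matplotlib
    import scipy
    import skimage
    import statsmodels

    from . import __version__

    return {
        "fluorplate": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "scikit-image": skimage.__version__,
        "matplotlib": matplotlib.__version__,
    }


def build_report(
    cf_table: pd.DataFrame,
    kinetics_table: pd.DataFrame | None,
    comparisons: list[ComparisonResult],
    output_dir: str | Path,
    group_column: str | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write plots, summary CSVs and a run manifest to ``output_dir``.

    Produces parameter-versus-time trace plots (grouped when
    ``group_column`` is present in ``cf_table``), a light-response panel
    when the table holds several PPFD levels, the input tables as CSV, a
    comparison summary, and ``manifest.json`` recording config, seed,
    package versions and SHA-256 hashes of the inputs.  An empty kinetics
    table omits that section with a warning.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(output_dir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {outdir}: {exc}") from exc
    paths: dict[str, Path] = {}

    paths["cf_table"] = outdir / "cf_table.csv"
    cf_table.to_csv(paths["cf_table"], index=False)
    hashes = {"cf_table": _sha256_of_frame(cf_table)}

    if kinetics_table is not None and len(kinetics_table):
        paths["kinetics"] = outdir / "kinetics.csv"
        kinetics_table.to_csv(paths["kinetics"], index=False)
        hashes["kinetics"] = _sha256_of_frame(kinetics_table)
    else:
        warnings.warn("kinetics table empty; section omitted from report",
                      RuntimeWarning, stacklevel=2)

    if comparisons:
        comp = pd.concat([c.to_frame() for c in comparisons], ignore_index=True)
        paths["comparisons"] = outdir / "comparisons.csv"
        comp.to_csv(paths["comparisons"], index=False)
        hashes["comparisons"] = _sha256_of_frame(comp)

    # time-trace panel
    trace_params = [p for p in ("fqp_fmp", "npq", "qp", "fvp_fmp")
                    if p in cf_table.columns]
    lit = cf_table[cf_table["npq"].notna()] if "npq" in cf_table.columns else cf_table
    if len(lit) and trace_params:
        fig, axes = plt.subplots(
            len(trace_params), 1, figsize=(7, 2.4 * len(trace_params)), sharex=True
        )
        axes = np.atleast_1d(axes)
        key = group_column if group_column and group_column in lit.columns else "sample_id"
        for ax, param in zip(axes, trace_params):
            agg = lit.groupby([key, "time_s"])[param].mean().reset_index()
            for name, sub in agg.groupby(key):
                ax.plot(sub["time_s"] / 60.0, sub[param], marker="o", ms=3,
                        label=str(name))
            ax.set_ylabel(param)
        axes[-1].set_xlabel("time (min)")
        axes[0].legend(fontsize=7, ncol=2)
        fig.tight_layout()
        paths["traces"] = outdir / "traces.png"
        fig.savefig(paths["traces"], dpi=120)
        plt.close(fig)
        # light-response panel when several PPFD levels are present
        if lit["ppfd"].nunique() > 2:
            fig, axes = plt.subplots(
                1, len(trace_params), figsize=(3.2 * len(trace_params), 3),
                sharex=True,
            )
            axes = np.atleast_1d(axes)
            for ax, param in zip(axes, trace_params):
                agg = lit.groupby([key, "ppfd"])[param].mean().reset_index()
                for name, sub in agg.groupby(key):
                    sub = sub.sort_values("ppfd")
                    ax.plot(sub["ppfd"], sub[param], marker="o", ms=3,
                            label=str(name))
                ax.set_xlabel("PPFD (µmol m$^{-2}$ s$^{-1}$)")
                ax.set_ylabel(param)
            axes[0].legend(fontsize=7)
            fig.tight_layout()
            paths["light_response"] = outdir / "light_response.png"
            fig.savefig(paths["light_response"], dpi=120)
            plt.close(fig)

    manifest = {
        "config": config or {},
        "seed": seed,
        "versions": _versions(),
        "input_hashes": hashes,
        "outputs": {k: str(v.name) for k, v in paths.items()},
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
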