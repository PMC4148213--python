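"""Downstream expression statistics: 2^-ddCt, allelic imbalance, luciferase.

Three quantitative comparisons support a cis-regulatory interpretation of a
candidate promoter variant:

* relative mRNA expression between genotype groups by the Livak
  2^-ddCt method with t-tests on delta-Ct;
* allelic expression imbalance (AEI) from pyrosequencing allele ratios,
  paired within individuals (cDNA vs gDNA) and unpaired between genotypes;
* promoter activity from dual-luciferase reporter assays normalised per
  biological repeat to a promoterless reference construct.

Welch's unequal-variance t-test is the default wherever a "Student's
t-test" is unspecific about variance pooling; ``equal_var=True`` switches
to the pooled form.  No multiple-testing correction is applied by default
(per-comparison reporting); a Bonferroni helper is exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


def bonferroni(p_values, n_tests: Optional[int] = None) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    m = n_tests if n_tests is not None else p.size
    return np.minimum(p * m, 1.0)


def _welch(a, b, equal_var: bool = False) -> float:
    if len(a) < 2 or len(b) < 2:
        return math.nan
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        # degenerate zero-variance input: no evidence of a difference unless
        # the (exactly constant) groups differ
        return 1.0 if a.mean() == b.mean() else 0.0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def _paired(a, b) -> float:
    if len(a) < 2:
        return math.nan
    diff = np.asarray(a, float) - np.asarray(b, float)
    if np.var(diff) == 0.0:
        return 1.0 if diff.mean() == 0.0 else 0.0
    return float(stats.ttest_rel(a, b).pvalue)


# ----------------------------------------------------------------------------
# relative expression (2^-ddCt)


@dataclass
class DdctResult:
    per_individual: pd.DataFrame  # individual, group, dct
    per_group: pd.DataFrame  # group, n, mean_dct, sd_dct, ddct, fold, p_value
    reference_group: str


def ddct_fold_change(ct: pd.DataFrame, reference_group: str,
                     equal_var: bool = False) -> DdctResult:
    """Per-group fold changes by the 2^-ddCt method with t-tests on delta-Ct.

    ``ct`` needs columns individual / group / gene / ct with gene in
    {target, reference}; technical replicates (extra rows) are averaged per
    individual and gene.  delta-Ct = Ct_target - Ct_reference per
    individual; delta-delta-Ct per group is the group mean delta-Ct minus
    the reference group's mean, so the reference group's fold is exactly 1.
    The test compares delta-Ct values between each group and the reference
    group (Welch by default); groups with n < 2 report fold but no test.
    """
    required = {"individual", "group", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    if reference_group not in set(ct["group"]):
        raise ValueError(f"reference group {reference_group!r} absent")

    mean_ct = (
        ct.groupby(["individual", "group", "gene"])["ct"].mean().unstack("gene")
    )
    for gene in ("target", "reference"):
        if gene not in mean_ct.columns or mean_ct[gene].isna().any():
            raise ValueError(f"every individual needs a {gene} Ct")
    dct = (mean_ct["target"] - mean_ct["reference"]).reset_index()
    dct.columns = ["individual", "group", "dct"]

    ref_dct = dct.loc[dct["group"] == reference_group, "dct"].to_numpy()
    rows = []
    for group, sub in dct.groupby("group", sort=False):
        values = sub["dct"].to_numpy()
        ddct = values.mean() - ref_dct.mean()
        if group == reference_group:
            ddct, p = 0.0, math.nan
        else:
            p = _welch(values, ref_dct, equal_var=equal_var)
        rows.append(
            {
                "group": group,
                "n": len(values),
                "mean_dct": values.mean(),
                "sd_dct": values.std(ddof=1) if len(values) > 1 else math.nan,
                "ddct": ddct,
                "fold": 2.0 ** (-ddct),
                "p_value": p,
            }
        )
    return DdctResult(dct, pd.DataFrame(rows), reference_group)


# ----------------------------------------------------------------------------
# allelic expression imbalance


@dataclass
class AeiResult:
    per_group: pd.DataFrame  # genotype, template, n, mean, sd
    within_genotype: pd.DataFrame  # genotype, n_pairs, p_value (paired, cDNA vs gDNA)
    between_genotypes: pd.DataFrame  # genotype_a, genotype_b, p_value (cDNA, Welch)


def aei_test(ratios: pd.DataFrame, equal_var: bool = False) -> AeiResult:
    """Allelic-imbalance statistics from paired gDNA/cDNA allele fractions.

    ``ratios`` needs columns individual / genotype / template /
    major_fraction with template in {gDNA, cDNA}.  Within each genotype the
    cDNA fraction is compared to the gDNA fraction paired on individual
    (individuals lacking one template are dropped with a warning); cDNA
    fractions are compared between genotypes with an unpaired test.  For
    homozygotes there is no allele contrast, but the same cDNA-vs-gDNA
    comparison quantifies assay signal bias.
    """
    required = {"individual", "genotype", "template", "major_fraction"}
    if not required.issubset(ratios.columns):
        raise ValueError(f"ratio table needs columns {sorted(required)}")
    frac = ratios["major_fraction"]
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("major_fraction must be in [0, 1]")

    per_group = (
        ratios.groupby(["genotype", "template"])["major_fraction"]
        .agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )

    within_rows = []
    for genotype, sub in ratios.groupby("genotype", sort=False):
        wide = sub.pivot_table(index="individual", columns="template",
                               values="major_fraction", aggfunc="mean")
        if not {"gDNA", "cDNA"}.issubset(wide.columns):
            within_rows.append({"genotype": genotype, "n_pairs": 0,
                                "p_value": math.nan})
            continue
        paired = wide.dropna(subset=["gDNA", "cDNA"])
        if len(paired) < len(wide):
            import warnings

            warnings.warn(
                f"{len(wide) - len(paired)} unpaired individual(s) dropped "
                f"from the paired test for genotype {genotype}",
                stacklevel=2,
            )
        p = _paired(paired["cDNA"].to_numpy(), paired["gDNA"].to_numpy())
        within_rows.append({"genotype": genotype, "n_pairs": len(paired),
                            "p_value": p})

    genotypes = list(dict.fromkeys(ratios["genotype"]))
    between_rows = []
    cdna = ratios[ratios["template"] == "cDNA"]
    for i, ga in enumerate(genotypes):
        for gb in genotypes[i + 1:]:
            a = cdna.loc[cdna["genotype"] == ga, "major_fraction"].to_numpy()
            b = cdna.loc[cdna["genotype"] == gb, "major_fraction"].to_numpy()
            between_rows.append(
                {"genotype_a": ga, "genotype_b": gb,
                 "p_value": _welch(a, b, equal_var=equal_var)}
            )
    return AeiResult(per_group, pd.DataFrame(within_rows),
                     pd.DataFrame(between_rows))


# ----------------------------------------------------------------------------
# luciferase reporter normalisation


@dataclass
class LuciferaseResult:
    per_construct: pd.DataFrame  # construct, n_repeats, mean_activity, sd_activity
    per_repeat: pd.DataFrame  # construct, repeat, activity
    tests: pd.DataFrame  # construct_a, construct_b, p_value


def luciferase_fold(lum: pd.DataFrame, reference_construct: str = "pGL3-Basic",
                    pairs: Optional[list[tuple[str, str]]] = None,
                    equal_var: bool = False) -> LuciferaseResult:
    """Normalised promoter activities from dual-luciferase luminescence.

    ``lum`` needs columns construct / firefly / renilla / technical /
    repeat.  Per well the ratio firefly/renilla is taken; per construct and
    biological repeat the technical-replicate ratios are averaged and
    divided by the reference construct's mean in that same repeat, so
    activity is invariant to rescaling all luminescence in a repeat.
    Repeats missing the reference construct are excluded with a warning.
    Pairwise tests (Welch by default) are computed on the per-repeat
    activities for the designated construct pairs.
    """
    required = {"construct", "firefly", "renilla", "technical", "repeat"}
    if not required.issubset(lum.columns):
        raise ValueError(f"luminescence table needs columns {sorted(required)}")
    if (lum["renilla"] <= 0).any():
        raise ValueError("renilla luminescence must be positive")

    lum = lum.assign(ratio=lum["firefly"] / lum["renilla"])
    per = lum.groupby(["construct", "repeat"])["ratio"].mean().reset_index()

    activities = []
    for rep, sub in per.groupby("repeat"):
        ref = sub.loc[sub["construct"] == reference_construct, "ratio"]
        if ref.empty:
            import warnings

            warnings.warn(f"repeat {rep} lacks the reference construct; excluded",
                          stacklevel=2)
            continue
        norm = sub.assign(activity=sub["ratio"] / float(ref.iloc[0]))
        activities.append(norm[["construct", "repeat", "activity"]])
    if not activities:
        raise ValueError(f"reference construct {reference_construct!r} never present")
    per_repeat = pd.concat(activities, ignore_index=True)

    per_construct = (
        per_repeat.groupby("construct")["activity"]
        .agg(n_repeats="count", mean_activity="mean",
             sd_activity=lambda x: x.std(ddof=1))
        .reset_index()
    )

    rows = []
    for a, b in pairs or []:
        va = per_repeat.loc[per_repeat["construct"] == a, "activity"].to_numpy()
        vb = per_repeat.loc[per_repeat["construct"] == b, "activity"].to_numpy()
        rows.append({"construct_a": a, "construct_b": b,
                     "p_value": _welch(va, vb, equal_var=equal_var)})
    tests = pd.DataFrame(rows, columns=["construct_a", "construct_b", "p_value"])
    return LuciferaseResult(per_construct, per_repeat, tests)
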