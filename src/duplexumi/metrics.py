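"""Performance evaluation statistics and down-sampling.

Implements the quantitative assessment of the duplex approach:

* precision (CV %) and trueness (bias %) per mutation and nominal level,
  with pass flags against the GMO-analysis acceptance thresholds
  (CV <= 25 %, relaxed to < 50 % below the 0.2 % level; |bias| <= 25 %);
* quasi-binomial regression of mutation frequency on nominal level
  (linearity of quantification), fitted on (successes, totals) count pairs
  so the moment dispersion estimate is well defined;
* Poisson regression with a fixed log-offset for the minimal-coverage
  (down-sampling) analysis, with likelihood-ratio chi-square tests per
  factor;
* the distance-from-UMI artefact trend (binned counts, Poisson fit);
* deterministic uniform down-sampling of read pairs (pairs kept intact).

Model-fit choices: logit link for the quasi-binomial (family stated, link
left open by convention -- identity available behind a flag) and
likelihood-ratio rather than Wald chi-square tests, for invariance to
parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "PerformanceReport",
    "ModelFit",
    "precision_trueness",
    "fit_quasibinomial",
    "fit_poisson_offset",
    "distance_to_umi_trend",
    "downsample_pairs",
    "downsample_fastq",
]

#: ENGL-style acceptance thresholds
CV_LIMIT_PCT = 25.0
CV_LIMIT_LOW_LEVEL_PCT = 50.0
LOW_LEVEL_THRESHOLD = 0.002  # 0.2 % relative concentration
BIAS_LIMIT_PCT = 25.0


@dataclass
class PerformanceReport:
    table: pd.DataFrame  # one row per (mutation, level)

    def all_pass(self) -> bool:
        return bool((self.table["precision_pass"] & self.table["trueness_pass"]).all())


@dataclass
class ModelFit:
    family: str
    params: pd.Series
    dispersion: float
    deviance: float
    fitted: np.ndarray
    factor_tests: dict[str, tuple[float, int, float]] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)
    result: object | None = None


def precision_trueness(frequencies: pd.DataFrame) -> PerformanceReport:
    """CV % and bias % per (mutation, level) across replicates.

    ``frequencies`` needs columns mutation, level, replicate, frequency;
    levels are copy-number ratios on the 0-1 scale.  CV uses the sample SD
    (n - 1 denominator); bias compares the replicate mean to the nominal
    level.
    """
    required = {"mutation", "level", "replicate", "frequency"}
    if not required.issubset(frequencies.columns):
        raise ValueError(f"need columns {sorted(required)}")
    rows = []
    for (mutation, level), grp in frequencies.groupby(["mutation", "level"], sort=True):
        f = grp["frequency"].to_numpy(dtype=float)
        if f.size < 2:
            raise ValueError(f"{mutation} @ {level}: need >= 2 replicates")
        mean = float(f.mean())
        sd = float(f.std(ddof=1))
        cv = 100.0 * sd / mean if mean > 0 else np.inf
        bias = 100.0 * (mean - level) / level
        cv_limit = CV_LIMIT_LOW_LEVEL_PCT if level < LOW_LEVEL_THRESHOLD else CV_LIMIT_PCT
        rows.append({
            "mutation": mutation, "level": level, "n_replicates": int(f.size),
            "mean_frequency": mean, "sd": sd, "cv_pct": cv, "bias_pct": bias,
            "precision_pass": (cv < cv_limit) if level < LOW_LEVEL_THRESHOLD else (cv <= cv_limit),
            "trueness_pass": abs(bias) <= BIAS_LIMIT_PCT,
        })
    return PerformanceReport(pd.DataFrame(rows))


def fit_quasibinomial(
    successes: Sequence[int],
    totals: Sequence[int],
    levels: Sequence[float],
    link: str = "logit",
) -> ModelFit:
    """Quasi-binomial regression of mutant fraction on nominal level.

    Fitted on untransformed (successes, totals) pairs; the dispersion is the
    Pearson chi-square divided by the residual degrees of freedom.
    """
    y = np.column_stack([np.asarray(successes, float),
                         np.asarray(totals, float) - np.asarray(successes, float)])
    x = np.asarray(levels, float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct levels")
    if link == "logit":
        fam = sm.families.Binomial()
    elif link == "identity":
        fam = sm.families.Binomial(link=sm.families.links.Identity())
    else:
        raise ValueError(f"unsupported link {link!r}")
    model = sm.GLM(y, sm.add_constant(x), family=fam)
    res = model.fit()
    # moment estimator: Pearson chi-square (count scale) / residual df
    dispersion = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else float("nan")
    return ModelFit(
        family="quasi_binomial",
        params=pd.Series(res.params, index=["intercept", "level"]),
        dispersion=dispersion,
        deviance=float(res.deviance),
        fitted=np.asarray(res.fittedvalues, float),
        result=res,
    )


def fit_poisson_offset(
    data: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    offset: str,
) -> ModelFit:
    """Poisson regression with a fixed log-offset and per-factor LRT.

    ``data[offset]`` (e.g. total duplex counts or total reads) enters as
    ``log(offset)`` with coefficient fixed at 1.  Each factor gets a
    likelihood-ratio chi-square test against the model without it.  A
    factor level whose counts are all zero makes the MLE diverge; such fits
    are flagged ``degenerate`` instead of silently claiming convergence.
    """
    counts = data[response].to_numpy()
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("response must contain non-negative integer counts")
    if (data[offset] <= 0).any():
        raise ValueError("offsets must be positive")
    degenerate = False
    for f in factors:
        if (data.groupby(f)[response].sum() == 0).any():
            degenerate = True

    log_off = np.log(data[offset].to_numpy(dtype=float))
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in factors)
    full = sm.GLM.from_formula(formula, data=data, family=sm.families.Poisson(),
                               offset=log_off).fit()
    tests: dict[str, tuple[float, int, float]] = {}
    for f in factors:
        rest = [g for g in factors if g != f]
        reduced_formula = f"{response} ~ " + (" + ".join(f"C({g})" for g in rest) if rest else "1")
        reduced = sm.GLM.from_formula(reduced_formula, data=data,
                                      family=sm.families.Poisson(), offset=log_off).fit()
        stat = 2.0 * (full.llf - reduced.llf)
        df = int(full.df_model - reduced.df_model)
        p = float(sps.chi2.sf(max(stat, 0.0), df)) if df > 0 else float("nan")
        tests[f] = (float(stat), df, p)
    return ModelFit(
        family="poisson_offset",
        params=pd.Series(full.params),
        dispersion=float(full.pearson_chi2 / full.df_resid) if full.df_resid > 0 else float("nan"),
        deviance=float(full.deviance),
        fitted=np.asarray(full.fittedvalues, float),
        factor_tests=tests,
        flags={"degenerate": degenerate},
        result=full,
    )


def distance_to_umi_trend(
    distances: Sequence[int],
    bin_width: int = 20,
    max_distance: int | None = None,
) -> tuple[pd.DataFrame, ModelFit]:
    """Bin artefact observations by distance from the UMI end of read 1 and
    fit a Poisson regression of bin count on bin midpoint.

    Bins are 1-20, 21-40, ... represented by their midpoints (10, 30, ...).
    A negative distance coefficient means artefacts concentrate toward the
    fragment end that carries the UMI adapter.  ``max_distance`` extends the
    binning over the full observable range (e.g. the read length) so that
    artefact-free far bins contribute their zero counts to the fit.
    """
    d = np.asarray(list(distances), dtype=int)
    if d.size == 0:
        raise ValueError("no distances supplied")
    if (d < 1).any():
        raise ValueError("distances are 1-based and must be >= 1")
    n_bins = int(np.ceil(max(int(d.max()), max_distance or 0) / bin_width))
    counts = np.bincount((d - 1) // bin_width, minlength=n_bins)
    starts = np.arange(n_bins) * bin_width + 1
    ends = starts + bin_width - 1
    mids = ends - bin_width / 2.0  # range 1-20 is represented by 10
    table = pd.DataFrame({"bin_start": starts, "bin_end": ends,
                          "midpoint": mids, "count": counts})
    res = sm.GLM(table["count"], sm.add_constant(table["midpoint"]),
                 family=sm.families.Poisson()).fit()
    fit = ModelFit(
        family="poisson",
        params=pd.Series(res.params.to_numpy(), index=["intercept", "distance"]),
        dispersion=float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else float("nan"),
        deviance=float(res.deviance),
        fitted=np.asarray(res.fittedvalues, float),
        result=res,
    )
    return table, fit


def downsample_pairs(
    pairs: Sequence,
    n_pairs: int,
    seed: int,
    n_subsamples: int = 3,
) -> list[list]:
    """Uniform sampling of read pairs without replacement, pairs intact.

    Returns ``n_subsamples`` independent subsets; subset ``i`` is a
    deterministic function of ``(seed, i)``.  Original ordering is kept.
    """
    total = len(pairs)
    if n_pairs > total:
        raise ValueError(f"cannot sample {n_pairs} from {total} pairs")
    out = []
    for i in range(n_subsamples):
        rng = np.random.default_rng([seed, i])
        idx = np.sort(rng.choice(total, size=n_pairs, replace=False))
        out.append([pairs[j] for j in idx])
    return out


def downsample_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    n_pairs: int,
    seed: int,
    out_dir: str | Path,
    n_subsamples: int = 3,
) -> list[tuple[Path, Path]]:
    """seqtk-style down-sampling of a FASTQ pair to ``n_pairs`` read pairs,
    written as ``sub{i}.R1/R2.fastq`` under ``out_dir``."""
    from .tagio import read_fastq_pairs

    pairs = list(read_fastq_pairs(r1_path, r2_path))
    subsets = downsample_pairs(pairs, n_pairs, seed, n_subsamples)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, subset in enumerate(subsets):
        p1 = out_dir / f"sub{i}.R1.fastq"
        p2 = out_dir / f"sub{i}.R2.fastq"
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for name, s1, q1, s2, q2 in subset:
                f1.write(f"@{name}/1\n{s1}\n+\n{q1}\n")
                f2.write(f"@{name}/2\n{s2}\n+\n{q2}\n")
        paths.append((p1, p2))
    return paths
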