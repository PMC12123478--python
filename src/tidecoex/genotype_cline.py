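"""Empirical arm: SNP scorability filters, diploid genotype scoring, and the
depth-cline mixed model.

Individuals are scored per locus as 1 (two copies of the allele typical of
the full-moon-timed strain, "FM"), 0 (two copies of the new-moon-typical
allele, "NM"), or 0.5 (heterozygous); the genotype score is the mean over
non-missing loci, so 1 = FM-like and 0 = NM-like.  Depth is recorded as
elevation in metres (decreasing toward the sea), so an FM-like score at
depth corresponds to a negative slope on the logit scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

logger = logging.getLogger(__name__)

#: Valid diploid call codes; integers 0/1/2 count copies of the FM allele.
CALL_SCORES = {"homFM": 1.0, "het": 0.5, "homNM": 0.0}
MISSING_CALLS = {"missing", "NA", "", ".", None}

FST_MIN = 0.3
MAJOR_FREQ_MIN = 0.8
MINOR_FREQ_MAX = 0.4


@dataclass(frozen=True)
class SiteSummary:
    """Per-SNP summary used by the scorability filters.

    ``fm_major_freq`` is the frequency of the major allele in the FM strain
    and ``nm_freq_of_that_allele`` the same allele's frequency in the NM
    strain.  ``coordinate`` breaks missingness ties deterministically.
    """

    locus_id: str
    snp_id: str
    fst: float
    fm_major_freq: float
    nm_freq_of_that_allele: float
    n_missing: int
    coordinate: int = 0

    def __post_init__(self) -> None:
        for name in ("fst", "fm_major_freq", "nm_freq_of_that_allele"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def _passes_frequency_filter(site: SiteSummary) -> bool:
    # major allele > 0.8 in one strain while that allele stays minor
    # (< 0.4) in the other strain; checked in both orientations
    fm_ok = site.fm_major_freq > MAJOR_FREQ_MIN and site.nm_freq_of_that_allele < MINOR_FREQ_MAX
    nm_major = max(site.nm_freq_of_that_allele, 1 - site.nm_freq_of_that_allele)
    nm_major_is_alt = site.nm_freq_of_that_allele < 0.5
    freq_in_fm_of_nm_major = 1 - site.fm_major_freq if nm_major_is_alt else site.fm_major_freq
    nm_ok = nm_major > MAJOR_FREQ_MIN and freq_in_fm_of_nm_major < MINOR_FREQ_MAX
    return fm_ok or nm_ok


def select_scorable_snps(sites: list[SiteSummary]) -> list[str]:
    """Apply the scorability filters and pick one SNP per locus.

    Filters, in order: drop SNPs with F_ST below 0.3; keep SNPs whose major
    allele exceeds frequency 0.8 in one strain while remaining below 0.4 in
    the other.  Within each surviving locus the SNP with the fewest missing
    genotypes is retained (ties broken by genomic coordinate, then SNP id).
    Returns the retained loci's ids in input order.
    """
    passing = [s for s in sites if s.fst >= FST_MIN and _passes_frequency_filter(s)]
    by_locus: dict[str, SiteSummary] = {}
    order: list[str] = []
    for s in passing:
        if s.locus_id not in by_locus:
            by_locus[s.locus_id] = s
            order.append(s.locus_id)
        else:
            cur = by_locus[s.locus_id]
            if (s.n_missing, s.coordinate, s.snp_id) < (cur.n_missing, cur.coordinate, cur.snp_id):
                by_locus[s.locus_id] = s
    if not order:
        warnings.warn("no SNPs pass the scorability filters", stacklevel=2)
    return order


def score_call(call) -> float:
    """Score a diploid call: homFM -> 1, het -> 0.5, homNM -> 0.

    Integer calls are interpreted as FM-allele copy counts (0, 1, 2).
    Missing calls (NA and friends) propagate as NaN.
    """
    if call is None or (not isinstance(call, str) and pd.isna(call)):
        return float("nan")
    if call in MISSING_CALLS:
        return float("nan")
    if isinstance(call, str):
        if call in CALL_SCORES:
            return CALL_SCORES[call]
        raise ValueError(f"unknown genotype call {call!r}")
    if call in (0, 1, 2):
        return call / 2.0
    raise ValueError(f"unknown genotype call {call!r}")


def genotype_score(calls) -> float:
    """Per-individual hybrid index: mean locus score over non-missing calls.

    Returns NaN for an all-missing individual (callers exclude and log it).
    """
    scores = np.array([score_call(c) for c in calls], dtype=float)
    if np.all(np.isnan(scores)):
        return float("nan")
    return float(np.nanmean(scores))


def score_table(table: pd.DataFrame, loci: list[str] | None = None) -> pd.Series:
    """Genotype scores for every individual in a genotype table.

    ``table`` has one row per individual and one column per locus (plus any
    metadata columns, which are ignored when ``loci`` is given).  Individuals
    with no scorable call are dropped with a logged reason.
    """
    if loci is None:
        meta = {"individual", "site", "depth"}
        loci = [c for c in table.columns if c not in meta]
    scores = table[loci].apply(lambda row: genotype_score(row.to_list()), axis=1)
    dropped = scores.index[scores.isna()]
    for idx in dropped:
        logger.info("individual %s excluded: all %d calls missing", idx, len(loci))
    return scores.dropna()


@dataclass
class ClineFit:
    """Result of the genotype-score-on-depth regression (logit link)."""

    slope: float
    intercept: float
    slope_se: float
    p_value: float
    site_variance: float
    method: str = "mixed_vb"
    converged: bool = True
    n_obs: int = 0

    def ci95(self) -> tuple[float, float]:
        return (self.slope - 1.96 * self.slope_se, self.slope + 1.96 * self.slope_se)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "p_value": self.p_value,
            "site_variance": self.site_variance,
            "method": self.method,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _fit_glm_cluster(data: pd.DataFrame) -> ClineFit:
    X = sm.add_constant(data["depth"])
    res = sm.GLM(data["score"], X, family=sm.families.Binomial()).fit(
        cov_type="cluster", cov_kwds={"groups": data["site"].to_numpy()}
    )
    slope = float(res.params["depth"])
    se = float(res.bse["depth"])
    p = 2 * stats.norm.sf(abs(slope / se)) if se > 0 else float("nan")
    return ClineFit(
        slope=slope,
        intercept=float(res.params["const"]),
        slope_se=se,
        p_value=float(p),
        site_variance=0.0,
        method="glm_cluster",
        converged=bool(res.converged),
        n_obs=len(data),
    )


def fit_depth_cline(scores, depths, sites) -> ClineFit:
    """Fit the depth cline: logit-link model of score on depth with a random
    intercept per sampling site.

    The primary fit is a variational-Bayes binomial mixed GLM; when it fails
    (separation, degenerate grouping) a fixed-effects binomial GLM with
    cluster-robust (by site) standard errors is used and flagged via
    ``method``.  Requires at least two distinct depths and two sites.
    """
    data = pd.DataFrame({
        "score": np.asarray(scores, dtype=float),
        "depth": np.asarray(depths, dtype=float),
        "site": np.asarray(sites),
    }).dropna()
    if data["depth"].nunique() < 2:
        raise ValueError("need at least two distinct depths")
    if data["site"].nunique() < 2:
        raise ValueError("need at least two sampling sites")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BinomialBayesMixedGLM.from_formula(
                "score ~ depth", {"site": "0 + C(site)"}, data
            )
            res = model.fit_vb()
        i = list(res.model.exog_names).index("depth")
        j = list(res.model.exog_names).index("Intercept")
        slope = float(res.fe_mean[i])
        se = float(res.fe_sd[i])
        if not np.isfinite(slope) or not np.isfinite(se) or se <= 0:
            raise RuntimeError("variational fit did not produce finite estimates")
        p = 2 * stats.norm.sf(abs(slope / se))
        site_sd = float(np.exp(res.vcp_mean[0]))
        return ClineFit(
            slope=slope,
            intercept=float(res.fe_mean[j]),
            slope_se=se,
            p_value=float(p),
            site_variance=site_sd**2,
            method="mixed_vb",
            converged=True,
            n_obs=len(data),
        )
    except Exception as exc:  # fall back, but keep the audit trail
        logger.warning("mixed fit failed (%s); using cluster-robust GLM", exc)
        fit = _fit_glm_cluster(data)
        fit.converged = False
        return fit


# ---------------------------------------------------------------------------
# I/O helpers

def read_genotype_table(path) -> pd.DataFrame:
    """Read a genotype table from TSV.

    Expected columns: ``individual``, ``site``, ``depth``, then one column
    per locus with calls in {homFM, het, homNM, NA} or FM-allele counts
    0/1/2.
    """
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "site": str})
    required = {"individual", "site", "depth"}
    if not required.issubset(df.columns):
        raise ValueError(f"genotype table must contain columns {sorted(required)}")
    return df


def write_genotype_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_vcf_genotypes(path, fm_alleles: dict[str, str]) -> pd.DataFrame:
    """Read diploid calls from a (plain-text) VCF.

    ``fm_alleles`` maps variant IDs to the allele (REF or ALT base string)
    typical of the FM strain; variants absent from the map are skipped.
    Returns a frame with one row per sample and one column per variant ID,
    cells holding FM-allele copy counts (0/1/2) or NaN for missing calls.
    """
    samples: list[str] = []
    loci: list[str] = []
    counts: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                counts = [[] for _ in samples]
                continue
            vid, ref, alt = fields[2], fields[3], fields[4]
            if vid not in fm_alleles:
                continue
            fm = fm_alleles[vid]
            if fm == ref:
                fm_idx = "0"
            elif fm in alt.split(","):
                fm_idx = str(alt.split(",").index(fm) + 1)
            else:
                raise ValueError(f"FM allele {fm!r} not present at {vid}")
            loci.append(vid)
            fmt = fields[8].split(":")
            gt_pos = fmt.index("GT")
            for s, cell in enumerate(fields[9:]):
                gt = cell.split(":")[gt_pos].replace("|", "/")
                if "." in gt:
                    counts[s].append(float("nan"))
                else:
                    counts[s].append(sum(a == fm_idx for a in gt.split("/")))
    return pd.DataFrame(
        {locus: [counts[s][i] for s in range(len(samples))] for i, locus in enumerate(loci)},
        index=pd.Index(samples, name="individual"),
    )
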