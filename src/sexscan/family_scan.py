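"""Family-based genome scan and heterogamety classification.

Given a genotyped F1 family (two parents plus sexed offspring), this module:

* filters sites to those called in at least half of each offspring sex;
* tests each site for genotype-sex association with a two-sided Fisher's
  exact test on the offspring allele-count table and a Weir-Cockerham
  theta between male and female offspring;
* classifies the inheritance system (XY vs ZW) from parentally informative
  sites: under male heterogamety the sire is heterozygous and the dam
  homozygous at sex-linked sites, and every son should match the sire while
  every daughter matches the dam (the mirror holds for ZW through the dam);
* reports per-offspring label switches between consecutive informative sites
  as candidate recombination breakpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .records import MISSING, GenotypeMatrix
from .stats import fisher_exact_2x2, weir_cockerham_theta
from .stats import sex_ratio_test  # noqa: F401  (re-exported: part of this module's surface)

LABELS = ("maternal", "paternal", "paternal-specific", "neither", "missing")


def filter_half_sex_rule(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep sites called in >= ceil(n/2) of male and of female offspring."""
    off = gm.offspring_mask()
    males = off & gm.sex_mask("male")
    females = off & gm.sex_mask("female")
    n_m, n_f = int(males.sum()), int(females.sum())
    if n_m == 0 and n_f == 0:
        raise ValueError("no sexed offspring in the matrix")
    called = gm.called()
    ok = ((called[:, males].sum(axis=1) >= math.ceil(n_m / 2))
          & (called[:, females].sum(axis=1) >= math.ceil(n_f / 2)))
    return gm.take_sites(ok)


def site_association(gm: GenotypeMatrix, alpha: float = 0.01) -> pd.DataFrame:
    """Per-site Fisher's exact p and Weir-Cockerham theta, offspring only.

    The 2x2 table counts ref/alt alleles in male vs female offspring;
    parents are excluded so the parental genotypes cannot bias the table.
    Monomorphic sites get theta = NaN and p = 1.  Returns a DataFrame with
    columns chrom, pos, fst, fet_p, n_males_called, n_females_called,
    significant.
    """
    off = gm.offspring_mask()
    males = np.flatnonzero(off & gm.sex_mask("male"))
    females = np.flatnonzero(off & gm.sex_mask("female"))
    if males.size == 0 or females.size == 0:
        raise ValueError("association test needs offspring of both sexes")

    g = gm.genotypes
    rows = []
    for i in range(gm.n_sites):
        gm_m = g[i, males]
        gm_f = g[i, females]
        called_m = (gm_m != MISSING).all(axis=1)
        called_f = (gm_f != MISSING).all(axis=1)
        am = gm_m[called_m].ravel()
        af = gm_f[called_f].ravel()
        m_alt, f_alt = int((am == 1).sum()), int((af == 1).sum())
        m_ref, f_ref = am.size - m_alt, af.size - f_alt
        if (m_alt + f_alt == 0) or (m_ref + f_ref == 0):
            p, theta = 1.0, np.nan
        else:
            p = fisher_exact_2x2(f_ref, f_alt, m_ref, m_alt)
            theta = weir_cockerham_theta(gm_m, gm_f)
        rows.append((gm.sites.at[i, "chrom"], gm.sites.at[i, "pos"], theta, p,
                     int(called_m.sum()), int(called_f.sum())))
    out = pd.DataFrame(rows, columns=["chrom", "pos", "fst", "fet_p",
                                      "n_males_called", "n_females_called"])
    out["significant"] = out["fet_p"] < alpha
    return out


@dataclass
class InheritanceReport:
    """Outcome of the XY/ZW inheritance classification."""

    model: str  # 'XY', 'ZW' or 'inconclusive'
    xy_concordance: float         # peak per-site concordance under XY
    zw_concordance: float         # peak per-site concordance under ZW
    site_table: pd.DataFrame      # per informative site: model, pos, concordance
    labels: pd.DataFrame          # informative sites x offspring label matrix
    breakpoints: dict             # offspring id -> list of (pos_left, pos_right)
    explanation: str = ""
    decision_threshold: float = 0.9
    xy_mean_concordance: float = np.nan  # aggregate over all informative calls
    zw_mean_concordance: float = np.nan


def _offspring_labels(geno_site: np.ndarray, het_parent: np.ndarray,
                      hom_parent: np.ndarray) -> list:
    """Label each offspring call against the informative parental pair."""
    het_set = frozenset(het_parent.tolist())
    hom_set = frozenset(hom_parent.tolist())
    specific = (het_set - hom_set)  # allele the homozygous parent lacks
    labels = []
    for a, b in geno_site:
        if a == MISSING or b == MISSING:
            labels.append("missing")
            continue
        s = frozenset((int(a), int(b)))
        if s == hom_set:
            labels.append("maternal")  # caller re-maps for ZW
        elif s == het_set:
            labels.append("paternal")
        elif len(specific) == 1 and s == frozenset(specific):
            labels.append("paternal-specific")
        else:
            labels.append("neither")
    return labels


def classify_inheritance(gm: GenotypeMatrix, assoc: pd.DataFrame,
                         alpha: float = 0.01,
                         decision_threshold: float = 0.9) -> InheritanceReport:
    """Classify the family's heterogamety from sex-associated sites.

    Candidate sites are those significant at ``alpha`` with both parents
    called.  XY-informative sites have a heterozygous sire and homozygous
    dam; each offspring is labelled by which parental genotype it matches
    ("paternal-specific" marks the YY-like homozygote for the allele the
    dam lacks).  Per-site concordance is the fraction of sons labelled
    paternal plus daughters labelled maternal among that site's non-missing
    calls; ZW mirrors the computation through the dam.  The model whose
    peak per-site concordance is larger is declared if the peak reaches
    ``decision_threshold`` (aggregate concordances over all informative
    calls are also reported, but linked sites far from the SD locus dilute
    them and they are not used for the decision).
    """
    sire = gm.parent_index("sire")
    dam = gm.parent_index("dam")
    off = np.flatnonzero(gm.offspring_mask())
    off_ids = gm.individuals["id"].to_numpy()[off]
    off_male = (gm.individuals["sex"].to_numpy()[off] == "male")

    sig = assoc["significant"].to_numpy()
    merged = gm.sites.merge(assoc[["chrom", "pos"]].assign(_sig=sig),
                            on=["chrom", "pos"], how="left")
    candidate = merged["_sig"].fillna(False).to_numpy(dtype=bool)
    g = gm.genotypes
    parents_called = ((g[:, sire] != MISSING).all(axis=1)
                      & (g[:, dam] != MISSING).all(axis=1))
    candidate &= parents_called

    sire_het = g[:, sire, 0] != g[:, sire, 1]
    dam_het = g[:, dam, 0] != g[:, dam, 1]
    xy_sites = np.flatnonzero(candidate & sire_het & ~dam_het)
    zw_sites = np.flatnonzero(candidate & dam_het & ~sire_het)

    def evaluate(site_idx: np.ndarray, het_parent: int, hom_parent: int,
                 het_is_male_parent: bool):
        rows, label_rows = [], []
        hits = calls = 0
        for i in site_idx:
            labels = _offspring_labels(g[i, off], g[i, het_parent], g[i, hom_parent])
            # 'maternal' from the helper means "matches the homozygous
            # parent", 'paternal' "matches the heterozygous parent";
            # re-map to true parent-of-origin wording for the report
            if het_is_male_parent:
                mapped = labels
            else:
                swap = {"maternal": "paternal", "paternal": "maternal",
                        "paternal-specific": "maternal-specific"}
                mapped = [swap.get(l, l) for l in labels]
            lab = np.array(labels)
            # under either model sons should match the het/hom parent in the
            # same way: the heterogametic-sex offspring matches the
            # heterogametic parent
            het_sex_off = off_male if het_is_male_parent else ~off_male
            ok = ((het_sex_off & (lab == "paternal"))
                  | (~het_sex_off & (lab == "maternal")))
            nm = lab != "missing"
            hits += int(ok.sum())
            calls += int(nm.sum())
            conc = ok.sum() / nm.sum() if nm.any() else np.nan
            rows.append((gm.sites.at[int(i), "chrom"], gm.sites.at[int(i), "pos"],
                         conc, int(nm.sum())))
            label_rows.append(mapped)
        table = pd.DataFrame(rows, columns=["chrom", "pos", "concordance", "n_called"])
        labels_df = pd.DataFrame(label_rows, columns=off_ids,
                                 index=table["pos"] if len(table) else None)
        # decision statistic: the peak per-site concordance.  Aggregating
        # over every significant site would dilute a true signal with
        # distantly linked sites (recombinant, or with the sex-specific
        # allele matching the homozygous parent), which is the mixed
        # pattern real families show away from the SD peak.
        peak = float(table["concordance"].max()) if len(table) else np.nan
        mean = hits / calls if calls else np.nan
        return peak, mean, table, labels_df

    xy_conc, xy_mean, xy_table, xy_labels = evaluate(xy_sites, sire, dam, True)
    zw_conc, zw_mean, zw_table, zw_labels = evaluate(zw_sites, dam, sire, False)

    if xy_sites.size == 0 and zw_sites.size == 0:
        return InheritanceReport(
            model="inconclusive", xy_concordance=np.nan, zw_concordance=np.nan,
            site_table=pd.DataFrame(columns=["model", "chrom", "pos",
                                             "concordance", "n_called"]),
            labels=pd.DataFrame(), breakpoints={},
            explanation="no parentally informative significant sites",
            decision_threshold=decision_threshold)

    scores = {"XY": xy_conc if not np.isnan(xy_conc) else -np.inf,
              "ZW": zw_conc if not np.isnan(zw_conc) else -np.inf}
    best = max(scores, key=scores.get)
    model = best if scores[best] >= decision_threshold else "inconclusive"
    explanation = ("" if model != "inconclusive" else
                   f"max concordance {scores[best]:.3f} below threshold "
                   f"{decision_threshold}")

    xy_table = xy_table.assign(model="XY")
    zw_table = zw_table.assign(model="ZW")
    non_empty = [t for t in (xy_table, zw_table) if len(t)]
    site_table = (pd.concat(non_empty, ignore_index=True) if non_empty
                  else xy_table)
    labels_df = xy_labels if best == "XY" else zw_labels

    breakpoints: dict = {}
    if len(labels_df):
        pos = labels_df.index.to_numpy()
        for oid in labels_df.columns:
            lab = labels_df[oid].to_numpy()
            keep = lab != "missing"
            p, l = pos[keep], lab[keep]
            bps = [(int(p[k]), int(p[k + 1]))
                   for k in range(len(l) - 1) if l[k] != l[k + 1]]
            breakpoints[oid] = bps

    return InheritanceReport(model=model,
                             xy_concordance=float(xy_conc) if xy_sites.size else np.nan,
                             zw_concordance=float(zw_conc) if zw_sites.size else np.nan,
                             site_table=site_table, labels=labels_df,
                             breakpoints=breakpoints, explanation=explanation,
                             decision_threshold=decision_threshold,
                             xy_mean_concordance=xy_mean, zw_mean_concordance=zw_mean)
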