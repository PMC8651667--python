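"""Candidate functional-gene discovery from clustered expression profiles.

A cluster is designated *functional* when it both contains at least one known
functional gene and is enriched (BH-adjusted p below alpha) for at least one
user-specified target term. Members of functional clusters that are absent
from the known list, have zero curated literature hits and positive tissue
expression evidence are predicted as novel functional gene candidates, ranked
by their peak postnatal z-score (the ranking criterion is this package's
choice and is flagged as such in the report).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gapstat import ClusterAssignment
from .io import EvidenceTable, GeneSetCollection, KnownGeneList, ValidationError
from .profiles import ProfileMatrix

logger = logging.getLogger(__name__)

CANDIDATE_COLUMNS = ["gene_id", "cluster", "literature_hits",
                     "expression_evidence", "score", "rank"]


@dataclass
class FunctionalCluster:
    cluster: int
    triggering_terms: list
    known_members: list


@dataclass
class CandidateReport:
    functional_clusters: dict  # cluster id -> FunctionalCluster
    candidates: pd.DataFrame  # CANDIDATE_COLUMNS (score/rank NaN until ranked)
    known_matches: pd.DataFrame  # cluster, n_known, known_genes
    summary: dict = field(default_factory=dict)
    ranking_note: str = ("score = max z over postnatal timepoints "
                        "(package default; not a published criterion)")


def designate_functional_clusters(assignment: ClusterAssignment,
                                  known: KnownGeneList,
                                  enrichment: pd.DataFrame,
                                  target_terms, alpha: float = 0.05,
                                  sets: GeneSetCollection | None = None,
                                  require_rising: bool = False,
                                  profiles: ProfileMatrix | None = None,
                                  postnatal_timepoints=None) -> dict:
    """Clusters with >= 1 known member AND >= 1 target term enriched at
    padj < alpha. Optionally also require a rising trend (mean postnatal z of
    the cluster's mean profile above its mean embryonic z)."""
    target_terms = list(target_terms)
    if sets is not None:
        missing = [t for t in target_terms if t not in sets]
        if missing:
            raise ValidationError(f"target term(s) not in gene-set collection: {missing}")
    out: dict[int, FunctionalCluster] = {}
    for c in range(1, assignment.K + 1):
        members = assignment.members(c)
        known_members = sorted(g for g in members if g in known)
        if not known_members:
            continue
        sub = enrichment[(enrichment["cluster"] == c)
                         & (enrichment["term_id"].isin(target_terms))
                         & (enrichment["padj"] < alpha)]
        if sub.empty:
            continue
        if require_rising:
            if profiles is None or postnatal_timepoints is None:
                raise ValidationError("rising-trend filter needs profiles and "
                                      "postnatal timepoints")
            prof = profiles.zscores.loc[[g for g in members
                                         if g in profiles.zscores.index]]
            post = [t for t in profiles.timepoints if t in set(postnatal_timepoints)]
            emb = [t for t in profiles.timepoints if t not in set(postnatal_timepoints)]
            if prof.empty or prof[post].mean().mean() <= prof[emb].mean().mean():
                continue
        out[c] = FunctionalCluster(cluster=c,
                                   triggering_terms=sorted(sub["term_id"].unique()),
                                   known_members=known_members)
    return out


def cross_reference_known(assignment: ClusterAssignment,
                          known: KnownGeneList) -> pd.DataFrame:
    """Per cluster: sorted known members and their count, plus a total row in
    the summary dict downstream (the assignment is a partition, so each known
    gene is counted at most once)."""
    rows = []
    for c in range(1, assignment.K + 1):
        matched = sorted(g for g in assignment.members(c) if g in known)
        rows.append({"cluster": c, "n_known": len(matched),
                     "known_genes": ",".join(matched)})
    return pd.DataFrame(rows)


def predict_candidates(functional_clusters: dict, assignment: ClusterAssignment,
                       known: KnownGeneList, evidence: EvidenceTable) -> CandidateReport:
    """Members of functional clusters that are not in the known list, have
    zero literature hits and positive expression evidence. Genes with no
    evidence row are conservatively treated as documented (excluded, logged)."""
    rows = []
    missing_evidence = []
    for c, fc in sorted(functional_clusters.items()):
        for g in sorted(assignment.members(c)):
            if g in known:
                continue
            if g not in evidence:
                missing_evidence.append(g)
                continue
            if evidence.is_candidate_evidence(g):
                rows.append({"gene_id": g, "cluster": c,
                             "literature_hits": evidence.literature_hits(g),
                             "expression_evidence": True,
                             "score": np.nan, "rank": np.nan})
    if missing_evidence:
        logger.info("no evidence rows for %d gene(s); treated as documented: %s",
                    len(missing_evidence), missing_evidence[:10])
    candidates = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    known_matches = cross_reference_known(assignment, known)
    report = CandidateReport(
        functional_clusters=functional_clusters,
        candidates=candidates,
        known_matches=known_matches,
        summary={
            "n_functional_clusters": len(functional_clusters),
            "n_known_matched": int(sum(len(fc.known_members)
                                       for fc in functional_clusters.values())),
            "n_known_matched_total": int(known_matches["n_known"].sum()),
            "n_candidates": len(candidates),
            "n_missing_evidence": len(missing_evidence),
        },
    )
    _check_report(report, known)
    return report


def _check_report(report: CandidateReport, known: KnownGeneList) -> None:
    cand = set(report.candidates["gene_id"])
    assert not (cand & set(known.genes)), "candidate overlaps known list"
    assert set(report.candidates["cluster"]).issubset(set(report.functional_clusters)), \
        "candidate from a non-designated cluster"


def rank_candidates(report: CandidateReport, profiles: ProfileMatrix,
                    postnatal_timepoints, score_fn=None) -> CandidateReport:
    """Order candidates by score (default: maximum z over postnatal
    timepoints), descending; ties broken by gene_id. ``score_fn`` may replace
    the default and receives the gene's z-score Series."""
    cand = report.candidates.copy()
    if cand.empty:
        return report
    post = [t for t in profiles.timepoints if t in set(postnatal_timepoints)]
    missing = [g for g in cand["gene_id"] if g not in profiles.zscores.index]
    if missing:
        raise ValidationError(f"candidate(s) missing from profiles: {missing}")
    if score_fn is None:
        score_fn = lambda z: float(z[post].max())  # noqa: E731
    cand["score"] = [score_fn(profiles.zscores.loc[g]) for g in cand["gene_id"]]
    cand = cand.sort_values(["score", "gene_id"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
    cand["rank"] = np.arange(1, len(cand) + 1)
    return CandidateReport(report.functional_clusters, cand, report.known_matches,
                           dict(report.summary), report.ranking_note)
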