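"""End-to-end orchestration of the discovery pipeline.

``discover`` wires the stages together: canonical-motif scanning, Markov
order selection on round #0, effective-length choice, the L-mer ledger
filters, cluster-head clustering of motif and non-motif L-mers, the
alone-fraction filter, and significance testing with BH-FDR and
shared-L-mer dedup.  Every stage's in/out counts are kept so a run can be
audited filter by filter; all randomness derives from one seed via stable
per-stage child seeds.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from .effective_length import KlProfile, effective_length
from .lmer_clustering import (
    MotifCluster, ClusterHead, alone_fraction_filter, build_cluster,
    cluster_all,
)
from .lmer_filters import (
    FilterConfig, LmerRecord, PipelineAbort, alone_occurrence_census,
    apply_ror_filter, classify_lmers, compute_enrichments, entropy_floor,
    initial_lmer_records, ledger_frame, match_intervals_by_oligo,
)
from .markov_background import MarkovModel, OrderSelectionReport, select_order
from .motif_model import Pwm, scan_sequences, write_meme
from .motif_significance import dmin, score_noncanonical_clusters
from .selex_io import SelexRound, count_kmers

logger = logging.getLogger(__name__)

#: per-column distance below which a canonical cluster is considered to
#: have reproduced its CIS-BP motif (sanity warning only)
CANONICAL_SIMILARITY_WARN = 0.15


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class DiscoveryResult:
    seed: int
    order_report: OrderSelectionReport
    model: MarkovModel
    kl_profile: KlProfile
    L: int
    records: list[LmerRecord]
    canonical_clusters: list[MotifCluster]
    noncanonical_clusters: list[MotifCluster]   # after alone filter
    significant: list[MotifCluster]             # after BH + dedup
    stage_counts: dict = field(default_factory=dict)


def discover(
    rounds: list[SelexRound],
    cisbp: list[Pwm],
    config: FilterConfig | None = None,
    seed: int = 0,
    max_clusters: int = 5,
    q: float = 0.05,
) -> DiscoveryResult:
    """Run the full discovery pipeline.

    ``rounds`` must be the ordered chain round #0 .. selected round;
    ``cisbp`` the TF's canonical motif collection.
    """
    if len(rounds) < 2:
        raise ValueError("need round 0 plus at least one selection round")
    if rounds[0].round_index != 0:
        raise ValueError("first round must be round #0")
    if not cisbp:
        raise ValueError("canonical motif set is empty")
    config = config or FilterConfig()
    counts: dict = {}
    round0, selected = rounds[0], rounds[-1]

    # canonical-motif occurrences in the selected round
    ids = [str(i) for i in range(selected.n_oligos)]
    matches = []
    for pwm in cisbp:
        matches.extend(
            scan_sequences(pwm, selected.oligos, pvalue=config.fimo_pvalue,
                           sequence_ids=ids)
        )
    if not matches:
        raise PipelineAbort(
            "no canonical-motif matches in the selected round"
        )
    counts["cisbp_matches"] = len(matches)

    order_report, model = select_order(
        round0, min_count=config.min_count,
        seed=child_seed(seed, "order_selection"),
    )
    profile = effective_length(selected, model, min_count=config.min_count)
    L = profile.chosen_L
    counts["optimal_order"] = order_report.optimal_order
    counts["effective_length"] = L

    floor = entropy_floor([m.matched_word for m in matches])
    table = count_kmers(selected, L)
    records, audit = initial_lmer_records(table, floor, config.min_count)
    counts["lmer_initial"] = audit
    compute_enrichments(records, table, model)
    classify_lmers(records, match_intervals_by_oligo(matches), selected, L)
    counts["after_classify"] = _klass_counts(records)

    round_tables = [count_kmers(r, L) for r in rounds]
    apply_ror_filter(records, round_tables, config.ror_floor)
    counts["after_ror"] = _klass_counts(records)
    alone_occurrence_census(records, selected, L)
    counts["after_alone_census"] = _klass_counts(records)

    motif_words = [r.word for r in records if r.klass == "motif"]
    nonmotif_words = [r.word for r in records if r.klass == "nonmotif"]
    canonical_clusters = cluster_all(
        motif_words, L, max_clusters=max_clusters, kind="canonical"
    )
    _warn_dissimilar_canonical(canonical_clusters, cisbp)
    noncanon_all = (
        cluster_all(nonmotif_words, L, max_clusters=max_clusters,
                    kind="noncanonical")
        if nonmotif_words else []
    )
    counts["canonical_clusters"] = len(canonical_clusters)
    counts["noncanonical_clusters_raw"] = len(noncanon_all)

    kept = alone_fraction_filter(
        noncanon_all, selected, canonical_clusters,
        min_alone_fraction=config.min_alone_fraction,
    )
    counts["noncanonical_clusters_alone"] = len(kept)
    significant = score_noncanonical_clusters(
        kept, canonical_clusters, cisbp, q=q
    )
    counts["significant"] = len(significant)
    return DiscoveryResult(
        seed=seed, order_report=order_report, model=model, kl_profile=profile,
        L=L, records=records, canonical_clusters=canonical_clusters,
        noncanonical_clusters=kept, significant=significant,
        stage_counts=counts,
    )


def _klass_counts(records) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in records:
        out[r.klass] = out.get(r.klass, 0) + 1
    return out


def _warn_dissimilar_canonical(clusters, cisbp) -> None:
    for c in clusters:
        d = dmin(c.pwm, cisbp)
        if d is None or d > CANONICAL_SIMILARITY_WARN:
            logger.warning(
                "canonical cluster %s is unexpectedly far from the CIS-BP "
                "motifs (D_min=%s)", c.head.word, d,
            )


# -- cluster serialization --------------------------------------------------


def write_clusters(clusters: list[MotifCluster], outdir, prefix: str) -> None:
    """Write cluster PWMs (MEME minimal) and a members TSV."""
    os.makedirs(outdir, exist_ok=True)
    named = []
    rows = []
    for i, c in enumerate(clusters):
        cid = f"{prefix}_{i}_{c.head.word}"
        named.append(Pwm(name=cid, matrix=c.pwm.matrix, source=c.pwm.source))
        for mb in c.members:
            rows.append((cid, c.head.word, c.head.l, c.head.m, c.kind,
                         mb.word, mb.offset, mb.orientation, mb.mismatches,
                         c.alone_fraction, c.dmin, c.pvalue, c.significant))
    if named:
        write_meme(named, os.path.join(outdir, f"{prefix}.meme"))
    pd.DataFrame(
        rows,
        columns=["cluster_id", "head", "l", "m", "kind", "word", "offset",
                 "orientation", "mismatches", "alone_fraction", "dmin",
                 "pvalue", "significant"],
    ).to_csv(os.path.join(outdir, f"{prefix}_members.tsv"), sep="\t",
             index=False)


def read_clusters(members_tsv) -> list[MotifCluster]:
    """Rebuild clusters (members + PWM) from a members TSV."""
    df = pd.read_csv(members_tsv, sep="\t")
    clusters = []
    for cid, grp in df.groupby("cluster_id", sort=False):
        first = grp.iloc[0]
        head = ClusterHead(word=first["head"], l=int(first["l"]),
                           m=int(first["m"]))
        cluster = build_cluster(head, list(grp["word"]), kind=first["kind"])
        if not pd.isna(first["alone_fraction"]):
            cluster.alone_fraction = float(first["alone_fraction"])
        if "dmin" in grp and not pd.isna(first["dmin"]):
            cluster.dmin = float(first["dmin"])
        clusters.append(cluster)
    return clusters


def write_outputs(result: DiscoveryResult, outdir) -> None:
    """Write the audit ledger, KL profile, clusters and summary TSVs."""
    os.makedirs(outdir, exist_ok=True)
    ledger_frame(result.records).to_csv(
        os.path.join(outdir, "lmer_ledger.tsv"), sep="\t", index=False
    )
    result.kl_profile.to_tsv(os.path.join(outdir, "kl_profile.tsv"))
    from .markov_background import write_model

    write_model(result.model, os.path.join(outdir, "markov_model.tsv"),
                seed=result.seed)
    write_clusters(result.canonical_clusters, outdir, "canonical")
    write_clusters(result.noncanonical_clusters, outdir, "noncanonical")
    write_clusters(result.significant, outdir, "significant")
    rows = []
    for c in result.significant:
        rows.append((f"sig_{c.head.word}", c.dmin, c.pvalue, c.significant,
                     c.alone_fraction, c.consensus))
    pd.DataFrame(
        rows, columns=["cluster_id", "dmin", "pvalue", "significant",
                       "alone_fraction", "consensus"],
    ).to_csv(os.path.join(outdir, "results.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "run_summary.tsv"), "w") as fh:
        fh.write(f"seed\t{result.seed}\n")
        fh.write(f"optimal_order\t{result.order_report.optimal_order}\n")
        fh.write(f"effective_length\t{result.L}\n")
        for key, val in result.stage_counts.items():
            fh.write(f"{key}\t{val}\n")
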