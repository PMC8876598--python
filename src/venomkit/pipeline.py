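"""End-to-end orchestration: QC -> annotate -> cluster -> segment -> families -> masses.

``run_pipeline`` consumes EST FASTA input (library and/or transcriptome),
a reference protein set and optional MALDI peak lists, and produces the
full table bundle plus a summary JSON whose internal identities
(category counts, cluster bookkeeping, non-redundant protein totals) are
enforced by ``summary_consistency_check``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import edlib
import pandas as pd

from . import annotate, cluster, family, framework, masscalc, precursor, seqio

log = logging.getLogger("venomkit")

CATEGORIES = ("toxin_like", "cellular", "no_match")


@dataclass
class RunConfig:
    """Every knob of a pipeline run; defaults match the package defaults."""

    library_fasta: str | None = None
    transcriptome_fasta: str | None = None
    refs_fasta: str | None = None
    peaklist_paths: list[str] = field(default_factory=list)
    signal_cuts_tsv: str | None = None
    out_dir: str = "venomkit_out"
    seed: int = 0
    qc_min_len: int = seqio.DEFAULT_QC_MIN_LEN
    evalue_cutoff: float = annotate.DEFAULT_EVALUE_CUTOFF
    min_orf_aa: int = annotate.DEFAULT_MIN_ORF_AA
    min_overlap_nt: int = cluster.DEFAULT_MIN_OVERLAP_NT
    min_identity_pct: float = cluster.DEFAULT_MIN_IDENTITY_PCT
    max_pro_len: int = precursor.DEFAULT_MAX_PRO_LEN
    pqm_acidic: str = "ED"
    family_identity_pct: float = family.DEFAULT_IDENTITY_THRESHOLD
    family_relaxed_pct: float = family.DEFAULT_RELAXED_IDENTITY
    framework_max_dist: int = family.DEFAULT_FRAMEWORK_MAX_DIST
    mass_tolerance_da: float = masscalc.DEFAULT_TOLERANCE_DA
    toxin_prefix: str = "HptTx"


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _best_orf(est: seqio.ESTRecord, ann: annotate.Annotation,
              min_orf_aa: int) -> annotate.Orf | None:
    for orf in annotate.translate_orfs(est, min_orf_aa=min_orf_aa):
        if orf.frame == ann.frame and orf.protein == ann.orf_protein:
            return orf
    return None


def run_pipeline(config: RunConfig,
                 ests: list[seqio.ESTRecord] | None = None,
                 refs: list[seqio.ReferenceEntry] | None = None,
                 peaklists: list[seqio.PeakList] | None = None) -> dict:
    """Execute the full analysis; returns the summary dict.

    Inputs may be given as in-memory objects (preferred for synthetic
    runs) or as paths on the config.  All tables are written under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------- load + QC
    try:
        if ests is None:
            ests = []
            if config.library_fasta:
                ests += seqio.load_ests(config.library_fasta, source="library")
            if config.transcriptome_fasta:
                ests += seqio.load_ests(config.transcriptome_fasta,
                                        source="transcriptome")
        if refs is None:
            if not config.refs_fasta:
                raise ValueError("a reference set is required")
            refs = seqio.load_references(config.refs_fasta)
        if peaklists is None:
            peaklists = [seqio.read_peaklist(p) for p in config.peaklist_paths]
    except StageError:
        raise
    except Exception as exc:
        raise StageError("load", str(exc)) from exc

    n_raw = len(ests)
    passing, failing = seqio.qc_filter(ests, config.qc_min_len)
    log.info("QC: %d raw ESTs, %d high-quality (> %d nt), %d discarded",
             n_raw, len(passing), config.qc_min_len, len(failing))

    # -------------------------------------------------------------- annotate
    try:
        annotations = [annotate.classify_est(
            est, refs, evalue_cutoff=config.evalue_cutoff,
            min_orf_aa=config.min_orf_aa) for est in passing]
    except Exception as exc:
        raise StageError("annotate", str(exc)) from exc
    ann_by_id = {a.est_id: a for a in annotations}
    cat_summary = cluster.summarize_categories(annotations)
    _write_annotations(annotations, out / "annotations.tsv")

    # --------------------------------------------------------------- cluster
    try:
        cluster_sets: dict[str, cluster.ClusterSet] = {}
        for cat in CATEGORIES:
            members = [e for e in passing
                       if ann_by_id[e.id].category == cat]
            cluster_sets[cat] = cluster.cluster_ests(
                members, config.min_overlap_nt, config.min_identity_pct,
                category=cat)
    except Exception as exc:
        raise StageError("cluster", str(exc)) from exc

    # ------------------------------------------------------------- precursor
    try:
        signal_cuts = (precursor.load_signal_cuts(config.signal_cuts_tsv)
                       if config.signal_cuts_tsv else {})
        precursors: list[precursor.ToxinPrecursor] = []
        prec_by_est: dict[str, precursor.ToxinPrecursor] = {}
        clone = 0
        for est in passing:
            ann = ann_by_id[est.id]
            if ann.category != "toxin_like":
                continue
            orf = _best_orf(est, ann, config.min_orf_aa)
            if orf is None:
                continue
            clone += 1
            ctx = precursor.OrfContext(
                has_start=orf.has_start, has_stop=orf.has_stop,
                source=est.source)
            prec = precursor.segment_precursor(
                est.id, orf.protein, ctx=ctx,
                signal_cut=signal_cuts.get(est.id),
                max_pro_len=config.max_pro_len, acidic=config.pqm_acidic)
            prec.est_id = est.id
            prec.name = annotate.name_toxin(
                clone, is_partial=prec.completeness != "full_length",
                from_transcriptome=est.source == "transcriptome",
                prefix=config.toxin_prefix)
            precursors.append(prec)
            prec_by_est[est.id] = prec
    except Exception as exc:
        raise StageError("precursor", str(exc)) from exc

    _refine_partials_by_cluster(precursors, prec_by_est,
                                cluster_sets["toxin_like"])

    proteins_by_est = {eid: p.full_seq for eid, p in prec_by_est.items()}
    for cat in ("cellular", "no_match"):
        for c in cluster_sets[cat].clusters:
            for eid in c.member_est_ids:
                proteins_by_est.setdefault(eid, ann_by_id[eid].orf_protein)
    for cs in cluster_sets.values():
        cs.bins = cluster.bin_table(cs, proteins_by_est)
    _write_cluster_report(cluster_sets, out / "clusters.tsv")

    # ---------------------------------------------------- framework + family
    try:
        frameworks = [framework.extract_framework(p.mature_seq)
                      for p in precursors]
        for fw in frameworks:
            framework.assign_template(fw)
        assignments = family.assign_families(
            precursors, frameworks,
            identity_threshold_pct=config.family_identity_pct,
            relaxed_identity_pct=config.family_relaxed_pct,
            framework_max_dist=config.framework_max_dist) if precursors else []
        toxin_refs = [r for r in refs if r.category == "toxin"]
        matures = [p.mature_seq for p in precursors if p.mature_seq]
        ident_hist = (family.identity_histogram(matures, toxin_refs)
                      if matures and toxin_refs else {})
    except Exception as exc:
        raise StageError("family", str(exc)) from exc
    _write_precursors(precursors, frameworks, assignments, out)

    # ------------------------------------------------------------------ mass
    try:
        candidates = []
        for p, fw in zip(precursors, frameworks):
            if not p.mature_seq or set(p.mature_seq) - masscalc.STANDARD_AA:
                continue
            pairs = None
            if fw.template_id:
                pairs = len(framework.template_by_id(fw.template_id).pairs)
            n_ss = masscalc.default_disulfide_count(fw.n_cys, pairs)
            candidates.append(masscalc.PeptideMass(
                sequence=p.mature_seq, n_disulfides=n_ss,
                amidated=p.amidated, name=p.name))
        mass_values = [c.mass_avg for c in candidates]
        mw_hist = masscalc.mw_distribution(mass_values)
        matches = []
        for pl in peaklists:
            matches += masscalc.match_peaks(pl, candidates,
                                            config.mass_tolerance_da)
        _write_mass_tables(candidates, matches, out)
    except Exception as exc:
        raise StageError("mass", str(exc)) from exc

    # --------------------------------------------------------------- summary
    nr_proteins = {
        cat: len({proteins_by_est[eid]
                  for c in cluster_sets[cat].clusters
                  for eid in c.member_est_ids
                  if proteins_by_est.get(eid)})
        for cat in CATEGORIES}
    nr_proteins["total"] = sum(nr_proteins[c] for c in CATEGORIES)

    summary = {
        "n_raw_ests": n_raw,
        "total_ests": len(passing),
        "categories": cat_summary,
        "clusters": {
            **{cat: _cluster_summary(cluster_sets[cat]) for cat in CATEGORIES},
            "overall": _overall_cluster_summary(cluster_sets),
        },
        "nonredundant_proteins": nr_proteins,
        "n_toxin_precursors": len(precursors),
        "n_families": len({a.family_label for a in assignments}),
        "identity_histogram": ident_hist,
        "mw_histogram": mw_hist,
        "n_peak_matches": len(matches),
        "params": {k: v for k, v in asdict(config).items()
                   if not isinstance(v, (list, dict)) or v},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    ok, violations = summary_consistency_check(summary)
    if not ok:
        raise StageError("summary", "; ".join(violations))
    return summary


def _refine_partials_by_cluster(precursors, prec_by_est,
                                toxin_clusters: cluster.ClusterSet,
                                max_edit_frac: float = 0.25) -> None:
    """Transfer segmentation from full-length contig-mates onto fragments.

    A 5'-truncated EST (or one whose start codon mutated away) usually
    co-clusters with intact copies of the same transcript.  Locating the
    fragment's translation inside a full-length cluster-mate's precursor
    fixes the mature-peptide start far more reliably than de novo signal
    heuristics on a headless sequence.  Point mutations are tolerated via
    an infix edit-distance alignment.
    """
    est_to_members: dict[str, list[str]] = {}
    for contig in toxin_clusters.clusters:
        for eid in contig.member_est_ids:
            est_to_members[eid] = contig.member_est_ids
    for prec in precursors:
        flagged = (prec.completeness in ("n_truncated", "mature_only")
                   or "signal_remnant" in prec.notes)
        mates = [prec_by_est[eid] for eid in est_to_members.get(prec.est_id, [])
                 if eid in prec_by_est and eid != prec.est_id
                 and prec_by_est[eid].completeness == "full_length"
                 and "signal_remnant" not in prec_by_est[eid].notes]
        if not mates:
            continue
        ref = max(mates, key=lambda p: (len(p.full_seq), p.est_id))
        # a fragment whose internal Met mimics a start codon looks
        # full-length but is conspicuously shorter than its cluster-mates
        disguised = len(ref.full_seq) - len(prec.full_seq) >= 3
        if not (flagged or disguised):
            continue
        if len(prec.full_seq) > len(ref.full_seq):
            continue
        res = edlib.align(prec.full_seq, ref.full_seq, mode="HW",
                          task="locations")
        if res["editDistance"] < 0 or \
                res["editDistance"] > max_edit_frac * len(prec.full_seq):
            continue
        offset = res["locations"][0][0]
        new_start = max(0, ref.mature[0] - offset)
        if new_start >= len(prec.full_seq):
            continue
        prec.signal = (0, new_start) if new_start else None
        prec.propeptide = None
        if prec.completeness == "c_truncated":
            amidated, trimmed = False, prec.full_seq[new_start:]
        else:
            from .precursor import detect_amidation
            amidated, trimmed = detect_amidation(prec.full_seq[new_start:])
        prec.amidated = amidated
        prec.mature = (new_start, new_start + len(trimmed))
        if "cluster_transfer" not in prec.notes:
            prec.notes.append("cluster_transfer")


def _cluster_summary(cs: cluster.ClusterSet) -> dict:
    return {
        "n_clusters": len(cs.clusters),
        "n_singletons": cs.n_singletons,
        "n_contigs": cs.n_contigs,
        "n_ests": cs.n_ests,
        "bins": cs.bins,
    }


def _overall_cluster_summary(cluster_sets: dict) -> dict:
    return {
        "n_clusters": sum(len(cs.clusters) for cs in cluster_sets.values()),
        "n_singletons": sum(cs.n_singletons for cs in cluster_sets.values()),
        "n_contigs": sum(cs.n_contigs for cs in cluster_sets.values()),
        "n_ests": sum(cs.n_ests for cs in cluster_sets.values()),
    }


def summary_consistency_check(summary: dict) -> tuple[bool, list[str]]:
    """Verify the arithmetic identities a summary must satisfy.

    * category counts sum to the EST total;
    * per cluster block: singletons + contigs == clusters, and the size-bin
      EST counts sum to the block's EST count;
    * per-category non-redundant protein counts sum to the reported total.

    Returns (pass, list of violated identities).  Only identities whose
    operands are present are checked, so partial summaries (e.g. published
    count tuples) can be validated too.
    """
    violations: list[str] = []

    cats = summary.get("categories") or {}
    if cats and "total_ests" in summary:
        total = sum(v["count"] for v in cats.values())
        if total != summary["total_ests"]:
            violations.append(
                f"category counts sum to {total} != total_ests {summary['total_ests']}")

    for name, block in (summary.get("clusters") or {}).items():
        if {"n_singletons", "n_contigs", "n_clusters"} <= set(block):
            if block["n_singletons"] + block["n_contigs"] != block["n_clusters"]:
                violations.append(
                    f"{name}: singletons {block['n_singletons']} + contigs "
                    f"{block['n_contigs']} != clusters {block['n_clusters']}")
        if "bins" in block and "n_ests" in block:
            bin_ests = sum(b["n_ests"] for b in block["bins"].values())
            if bin_ests != block["n_ests"]:
                violations.append(
                    f"{name}: bin ESTs {bin_ests} != category ESTs {block['n_ests']}")

    nr = summary.get("nonredundant_proteins") or {}
    if "total" in nr:
        parts = sum(v for k, v in nr.items() if k != "total")
        if parts != nr["total"]:
            violations.append(
                f"non-redundant proteins {parts} != reported total {nr['total']}")

    return not violations, violations


# ----------------------------------------------------------------- writers

def _write_annotations(annotations, path: Path) -> None:
    pd.DataFrame([{
        "est_id": a.est_id, "category": a.category, "best_hit": a.best_hit_id,
        "score": a.score, "evalue": a.evalue,
        "identity_pct": round(a.identity_pct, 2), "frame": a.frame,
        "secondary_hit": a.secondary_hit,
    } for a in annotations]).to_csv(path, sep="\t", index=False)


def _write_cluster_report(cluster_sets, path: Path) -> None:
    rows = []
    for cat, cs in cluster_sets.items():
        for c in cs.clusters:
            rows.append({
                "category": cat, "contig_id": c.id, "size": c.size,
                "bin": cluster.size_bin(c.size),
                "n_unique_genes": len(c.unique_gene_seqs),
                "n_unique_proteins": len(c.unique_protein_seqs),
                "members": ",".join(c.member_est_ids),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_precursors(precursors, frameworks, assignments, out: Path) -> None:
    fam_by_name = {a.toxin_name: a for a in assignments}
    rows = []
    for p, fw in zip(precursors, frameworks):
        fa = fam_by_name.get(p.name)
        rows.append({
            "name": p.name, "est_id": p.est_id, "completeness": p.completeness,
            "signal": p.signal_seq, "propeptide": p.propeptide_seq,
            "mature": p.mature_seq, "amidated": p.amidated,
            "n_cys": fw.n_cys, "framework": fw.notation,
            "template": fw.template_id or "",
            "family": fa.family_label if fa else "",
            "notes": ";".join(p.notes + fw.notes),
        })
    pd.DataFrame(rows).to_csv(out / "precursors.tsv", sep="\t", index=False)
    seqio.write_fasta([(p.name, p.mature_seq) for p in precursors
                       if p.mature_seq], out / "matures.fasta")


def _write_mass_tables(candidates, matches, out: Path) -> None:
    pd.DataFrame([{
        "name": c.name, "sequence": c.sequence, "n_disulfides": c.n_disulfides,
        "amidated": c.amidated, "mass_avg": round(c.mass_avg, 4),
        "mass_mono": round(c.mass_mono, 4),
    } for c in candidates]).to_csv(out / "masses.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "peak_mz": m.peak_mz, "candidate": m.candidate,
        "interpretation": m.charge_interpretation,
        "theoretical": round(m.theoretical_mass, 4),
        "observed": round(m.observed_mass, 4),
        "delta_da": round(m.delta_da, 4),
    } for m in matches]).to_csv(out / "peak_matches.tsv", sep="\t", index=False)
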