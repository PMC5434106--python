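"""End-to-end orchestration: curation -> phylogeny -> genus validation ->
primer-pair coverage -> amplicon classification, from one config.

Every stage writes its intermediate artifact into the output directory and
appends counts to a deterministic run log, so two runs with the same config
and seed produce byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import curation, nbc, phylogeny
from .core_io import (
    MultipleAlignment,
    ReferenceSequence,
    TaxonSet,
    attach_taxonomy,
    read_alignment_fasta,
    read_fasta,
    read_primer_table,
    read_taxonomy_table,
    write_alignment_fasta,
    write_fasta,
)
from .primers import (
    AmpliconRecord,
    PrimerPair,
    assign_size_class,
    coverage_by_taxon,
    coverage_histogram,
    evaluate_pair,
    filter_min_coverage,
    nominal_amplicon_length,
    overall_coverage,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "make_report",
           "load_pipeline_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and parameters for one full analysis run."""

    fasta: Path
    taxonomy: Path
    primers: Path
    template: Path
    out_dir: Path
    outgroup_genus: str
    identity_threshold: float = 0.97
    max_gap_fraction: float = 0.90
    correction: str = "jukes_cantor"
    bootstrap_reps: int = 100
    min_coverage: float = 0.95
    word_size: int = 8
    nbc_boot: int = 100
    seed: int = 0
    assign: str = "first"
    min_len: int = 50
    max_len: int = 3000

    def validate(self) -> None:
        for name in ("identity_threshold", "max_gap_fraction", "min_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.bootstrap_reps < 0 or self.nbc_boot < 0:
            raise ValueError("replicate counts must be >= 0")
        if self.word_size < 1:
            raise ValueError("word_size must be >= 1")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key = value`` pipeline config file."""
    kv: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
    paths = {"fasta", "taxonomy", "primers", "template", "out_dir"}
    ints = {"bootstrap_reps", "word_size", "nbc_boot", "seed", "min_len", "max_len"}
    floats = {"identity_threshold", "max_gap_fraction", "min_coverage"}
    kwargs: dict = {}
    for key, val in kv.items():
        if key in paths:
            kwargs[key] = Path(val)
        elif key in ints:
            kwargs[key] = int(val)
        elif key in floats:
            kwargs[key] = float(val)
        elif key in {"outgroup_genus", "correction", "assign"}:
            kwargs[key] = val
        else:
            raise ValueError(f"unknown config key {key!r}")
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


@dataclass
class PipelineResult:
    """Everything a run produced, for reporting and assertions."""

    config: PipelineConfig
    records: list[ReferenceSequence]
    dereplicated: list[ReferenceSequence]
    otus: list[curation.OTU]
    tree: object  # skbio TreeNode
    clade_reports: list[phylogeny.CladeReport]
    taxon_sets: list[TaxonSet]
    coverage: pd.DataFrame
    size_classes: dict[str, str]
    survivors: list[str]
    overall: dict[str, float]
    recommended_pair: PrimerPair | None
    amplicons: list[AmpliconRecord]
    classification: pd.DataFrame | None
    histogram: pd.DataFrame
    log_lines: list[str] = field(default_factory=list)


def _dereplicate_alignment(
    aln: MultipleAlignment,
    meta: Mapping[str, ReferenceSequence],
) -> tuple[MultipleAlignment, dict[str, list[str]], dict[str, bool]]:
    """Collapse identical aligned rows; returns (alignment, groups, type flags).

    The surviving id is the first-seen row; ``groups`` maps it to every
    merged id and the type-strain flag is OR-ed across the group.
    """
    first: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    flags: dict[str, bool] = {}
    ids: list[str] = []
    rows: list[str] = []
    for rid, row in zip(aln.ids, aln.rows):
        if row in first:
            keep = first[row]
            groups[keep].append(rid)
            flags[keep] = flags[keep] or meta[rid].is_type_strain
        else:
            first[row] = rid
            groups[rid] = [rid]
            flags[rid] = meta[rid].is_type_strain
            ids.append(rid)
            rows.append(row)
    return MultipleAlignment(ids=tuple(ids), rows=tuple(rows)), groups, flags


def _realized_size_class(
    pair: PrimerPair,
    refs: Mapping[str, ReferenceSequence],
    member_ids: Sequence[str],
    min_len: int,
    max_len: int,
) -> str:
    lengths = []
    for mid in member_ids:
        amp = evaluate_pair(pair, refs[mid], min_len, max_len)
        if amp is not None:
            lengths.append(amp.length)
    if not lengths:
        return "unknown"
    lengths.sort()
    median = lengths[len(lengths) // 2]
    return assign_size_class(median)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write all artifacts under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed={config.seed}"]

    def _stage(fmt: str, *args) -> None:
        log.append(fmt % args)

    # --- inputs -----------------------------------------------------------
    records = attach_taxonomy(
        read_fasta(config.fasta), read_taxonomy_table(config.taxonomy)
    )
    pairs = read_primer_table(config.primers)
    if not pairs:
        raise ValueError("no primer pairs in primer table")
    template = read_alignment_fasta(config.template)
    _stage("input: %d sequences, %d primer pairs", len(records), len(pairs))

    # --- curation ---------------------------------------------------------
    derep = curation.dereplicate(records)
    _stage("dereplicate: %d unique sequences", len(derep))
    otus = curation.cluster_otus(derep, config.identity_threshold, config.assign)
    assert sum(len(o.member_ids) for o in otus) == len(derep)
    _stage("cluster: %d OTUs at %.2f identity", len(otus), config.identity_threshold)

    refs = {r.id: r for r in derep}
    rep_ids = [o.representative_id for o in otus]
    type_ids = [r.id for r in derep if r.is_type_strain]
    tree_input_ids = list(dict.fromkeys(rep_ids + type_ids))
    tree_input = [refs[i] for i in tree_input_ids]
    _stage("representatives+type strains: %d sequences", len(tree_input))

    aligned, discarded, dropped = curation.align_to_template(tree_input, template)
    _stage("align: %d aligned, %d dropped, %d inserted bases discarded",
           len(aligned), len(dropped), sum(discarded.values()))
    filtered, removed_cols = curation.filter_gap_columns(aligned, config.max_gap_fraction)
    _stage("gap filter: %d columns removed, width %d -> %d",
           len(removed_cols), aligned.width, filtered.width)
    final_aln, leaf_groups, leaf_is_type = _dereplicate_alignment(filtered, refs)
    _stage("post-filter dereplicate: %d alignment rows", len(final_aln))

    # --- phylogeny and genus validation -----------------------------------
    tree = phylogeny.bootstrap_support(
        final_aln, n_reps=config.bootstrap_reps, seed=config.seed,
        correction=config.correction,
    )
    genus_labels = {rid: refs[rid].genus for rid in final_aln.ids}
    outgroup_candidates = sorted(
        rid for rid in final_aln.ids
        if leaf_is_type[rid] and genus_labels[rid] == config.outgroup_genus
    )
    if not outgroup_candidates:
        raise ValueError(
            f"no type-strain leaf for outgroup genus {config.outgroup_genus!r}"
        )
    outgroup_id = outgroup_candidates[0]
    target_genera = sorted(
        {genus_labels[rid] for rid in final_aln.ids
         if leaf_is_type[rid] and genus_labels[rid]
         and genus_labels[rid] != config.outgroup_genus}
    )
    clade_reports = []
    for genus in target_genera:
        anchors = sorted(
            rid for rid in final_aln.ids
            if leaf_is_type[rid] and genus_labels[rid] == genus
        )
        clade_reports.append(
            phylogeny.check_monophyly(tree, genus, anchors, outgroup_id, genus_labels)
        )
    _stage("monophyly: %d/%d genera monophyletic",
           sum(r.is_monophyletic for r in clade_reports), len(clade_reports))

    # --- validated taxon sets (all sequences within each selected OTU) ----
    otu_by_rep = {o.representative_id: o for o in otus}
    taxon_sets: list[TaxonSet] = []
    for report in clade_reports:
        members: set[str] = set()
        for leaf in sorted(report.selected_ids):
            for rid in leaf_groups.get(leaf, [leaf]):
                otu = otu_by_rep.get(rid)
                members |= set(otu.member_ids) if otu else {rid}
        if members:
            taxon_sets.append(TaxonSet(name=report.genus, member_ids=frozenset(members)))
    if not taxon_sets:
        raise ValueError("no validated taxon sets; nothing to evaluate primers on")
    _stage("validated sets: %s",
           ", ".join(f"{t.name}:{len(t.member_ids)}" for t in taxon_sets))

    # --- primer evaluation -------------------------------------------------
    all_member_ids = sorted(set().union(*(t.member_ids for t in taxon_sets)))
    coverage = pd.concat(
        [coverage_by_taxon(p, taxon_sets, refs, config.min_len, config.max_len)
         for p in pairs],
        ignore_index=True,
    )
    size_classes: dict[str, str] = {}
    for p in pairs:
        size_classes[p.pair_id] = (
            p.size_class if p.size_class != "unknown"
            else _realized_size_class(p, refs, all_member_ids,
                                      config.min_len, config.max_len)
        )
    survivors = filter_min_coverage(coverage, config.min_coverage)
    overall = {
        pid: overall_coverage(next(p for p in pairs if p.pair_id == pid), refs,
                              config.min_len, config.max_len)
        for pid in survivors
    }
    _stage("coverage filter: %d/%d pairs >= %.2f for every taxon",
           len(survivors), len(pairs), config.min_coverage)
    histogram = coverage_histogram(coverage, size_classes)

    # --- recommended pair and amplicon classification ----------------------
    medium = [pid for pid in survivors if size_classes[pid] == "medium"]
    recommended = None
    if medium:
        mean_cov = coverage.groupby("pair_id")["coverage"].mean()

        def rank(pid: str):
            pair = next(p for p in pairs if p.pair_id == pid)
            nominal = nominal_amplicon_length(pair)
            return (-mean_cov[pid], nominal if nominal is not None else 10 ** 9, pid)

        recommended = next(p for p in pairs if p.pair_id == min(medium, key=rank))
        _stage("recommended pair: %s (mean coverage %.4f)",
               recommended.pair_id, mean_cov[recommended.pair_id])
    else:
        _stage("recommended pair: none (no medium-class pair passed the filter)")

    amplicons: list[AmpliconRecord] = []
    classification = None
    if recommended is not None:
        genus_of_member = {
            mid: t.name for t in taxon_sets for mid in t.member_ids
        }
        for mid in all_member_ids:
            amp = evaluate_pair(recommended, refs[mid], config.min_len, config.max_len)
            if amp is not None:
                amplicons.append(amp)
        train_records = [
            dataclasses.replace(
                refs[mid],
                taxonomy=refs[mid].taxonomy[:-1] + (genus_of_member[mid],)
                if refs[mid].taxonomy else ("Bacteria", genus_of_member[mid]),
            )
            for mid in all_member_ids
        ]
        model = nbc.train(train_records, k=config.word_size)
        classification = nbc.evaluate_amplicon_classification(
            model,
            [(a.seq_id, a.amplicon_seq, genus_of_member[a.seq_id]) for a in amplicons],
            n_boot=config.nbc_boot,
            seed=config.seed,
        )
        _stage("classification: %d amplicons, mean genus accuracy %.4f",
               len(amplicons), float(classification["fraction_correct"].mean()))

    result = PipelineResult(
        config=config, records=records, dereplicated=derep, otus=otus, tree=tree,
        clade_reports=clade_reports, taxon_sets=taxon_sets, coverage=coverage,
        size_classes=size_classes, survivors=survivors, overall=overall,
        recommended_pair=recommended, amplicons=amplicons,
        classification=classification, histogram=histogram, log_lines=log,
    )
    _write_artifacts(result, derep, final_aln, out)
    return result


def _write_artifacts(
    result: PipelineResult,
    derep: list[ReferenceSequence],
    final_aln: MultipleAlignment,
    out: Path,
) -> None:
    write_fasta(derep, out / "dereplicated.fasta")
    with (out / "otus.tsv").open("w") as fh:
        fh.write("#otu\trepresentative\tmembers\n")
        for i, otu in enumerate(result.otus):
            fh.write(f"{i}\t{otu.representative_id}\t"
                     f"{';'.join(sorted(otu.member_ids))}\n")
    write_alignment_fasta(final_aln, out / "filtered_alignment.fasta")
    with (out / "tree.nwk").open("w") as fh:
        fh.write(phylogeny.tree_to_newick(result.tree) + "\n")
    with (out / "clades.tsv").open("w") as fh:
        fh.write("#genus\tmonophyletic\tsupport\tn_clade\tn_selected\n")
        for r in result.clade_reports:
            sup = "" if r.support is None else f"{r.support:.1f}"
            fh.write(f"{r.genus}\t{int(r.is_monophyletic)}\t{sup}\t"
                     f"{len(r.clade_member_ids)}\t{len(r.selected_ids)}\n")
    with (out / "taxon_sets.tsv").open("w") as fh:
        fh.write("#genus\tn_members\tmembers\n")
        for t in result.taxon_sets:
            fh.write(f"{t.name}\t{len(t.member_ids)}\t"
                     f"{';'.join(sorted(t.member_ids))}\n")
    result.coverage.to_csv(out / "coverage.tsv", sep="\t", index=False)
    with (out / "size_classes.tsv").open("w") as fh:
        fh.write("#pair_id\tsize_class\n")
        for pid in sorted(result.size_classes):
            fh.write(f"{pid}\t{result.size_classes[pid]}\n")
    with (out / "survivors.tsv").open("w") as fh:
        fh.write("#pair_id\toverall_coverage\n")
        for pid in result.survivors:
            fh.write(f"{pid}\t{result.overall[pid]:.6f}\n")
    result.histogram.to_csv(out / "histogram.tsv", sep="\t", index=False)
    if result.amplicons:
        amp_records = [
            ReferenceSequence(
                id=f"{a.seq_id}|{a.pair_id}|{a.start}-{a.end}",
                sequence=a.amplicon_seq,
            )
            for a in result.amplicons
        ]
        write_fasta(amp_records, out / "amplicons.fasta")
    if result.classification is not None:
        result.classification.to_csv(out / "classification.tsv", sep="\t", index=False)
    with (out / "run.log").open("w") as fh:
        fh.write("\n".join(result.log_lines) + "\n")


def make_report(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Human-readable summary, ranked pair table and coverage histogram figure.

    Regenerating the report from the same result is byte-identical (figure
    metadata carries no timestamps).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "hcbprimer"

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": out / "report.txt",
        "ranked": out / "ranked_pairs.tsv",
        "figure": out / "coverage_histograms.svg",
    }

    cov = result.coverage
    mean_cov = cov.groupby("pair_id", sort=False)["coverage"].mean()
    min_cov = cov.groupby("pair_id", sort=False)["coverage"].min()
    ranked = pd.DataFrame({
        "pair_id": mean_cov.index,
        "size_class": [result.size_classes[p] for p in mean_cov.index],
        "mean_coverage": mean_cov.values,
        "min_coverage": min_cov.values,
        "passed_filter": [p in result.survivors for p in mean_cov.index],
    }).sort_values(["mean_coverage", "pair_id"], ascending=[False, True])
    ranked.to_csv(paths["ranked"], sep="\t", index=False)

    lines = ["Primer-pair coverage evaluation", "=" * 31, ""]
    lines += result.log_lines + [""]
    lines.append("Validated taxa: " + ", ".join(
        f"{t.name} (n={len(t.member_ids)})" for t in result.taxon_sets))
    lines.append(f"Pairs passing the {result.config.min_coverage:.0%} "
                 f"per-taxon filter: {len(result.survivors)}")
    for pid in result.survivors:
        lines.append(f"  {pid}: overall coverage {result.overall[pid]:.3f}")
    if result.recommended_pair is not None:
        nominal = nominal_amplicon_length(result.recommended_pair)
        lines.append(
            f"Recommended pair: {result.recommended_pair.pair_id} "
            f"({result.recommended_pair.forward.name} / "
            f"{result.recommended_pair.reverse.name}), "
            f"nominal amplicon {nominal if nominal else 'n/a'} bp"
        )
    if result.classification is not None:
        lines.append("")
        lines.append("Amplicon classification accuracy per genus:")
        for _, row in result.classification.iterrows():
            lines.append(
                f"  {row['genus']}: {row['fraction_correct']:.3f} correct "
                f"({int(row['n_correct'])}/{int(row['n'])}), "
                f"confident fraction {row['fraction_confident']:.3f}"
            )
    paths["summary"].write_text("\n".join(lines) + "\n")

    taxa = sorted(cov["taxon"].unique())
    classes = ["small", "medium", "large", "unknown"]
    present = [c for c in classes if c in set(result.size_classes.values())]
    fig, axes = plt.subplots(
        len(taxa), max(len(present), 1),
        figsize=(3 * max(len(present), 1), 2.2 * len(taxa)),
        squeeze=False,
    )
    bins = list(range(0, 101, 10))
    for ti, taxon in enumerate(taxa):
        for ci, cls in enumerate(present):
            ax = axes[ti][ci]
            pids = [p for p, c in result.size_classes.items() if c == cls]
            vals = cov[(cov["taxon"] == taxon) & (cov["pair_id"].isin(pids))][
                "coverage"] * 100
            ax.hist(vals, bins=bins, edgecolor="black")
            if ti == 0:
                ax.set_title(cls)
            if ci == 0:
                ax.set_ylabel(taxon, fontsize=8)
    fig.suptitle("Primer-pair coverage per taxon and amplicon size class")
    fig.tight_layout()
    fig.savefig(paths["figure"], metadata={"Date": None})
    plt.close(fig)
    return paths
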