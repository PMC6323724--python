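"""End-to-end orchestration: simulate -> filter -> groups -> reconcile ->
ancestral states -> conservation -> contacts -> report.

Every stage consumes and produces plain files under one output directory,
so any stage can be re-run independently from prior outputs.  A run with a
fixed configuration and seed reproduces every data output byte-identically;
wall-clock timings are confined to ``report.txt`` and the log, keeping
``report.json`` deterministic.
"""

from __future__ import annotations

import csv
import glob
import json
import logging
import os
import time
from dataclasses import asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import ancestral, conservation, contacts, identify, reconcile, simulate, trees
from .errors import EmptyFamilyError, InvalidInputError

log = logging.getLogger("septevo")

STAGES = ("simulate", "filter", "groups", "reconcile", "asr", "conserve", "contacts")

_CONFIG_KEYS = set(simulate.SimulationConfig.__dataclass_fields__) | {
    "outdir",
    "stages",
    "support_threshold",
    "min_taxa",
    "probe_diameter",
    "background",
}


def load_config(path: Optional[str] = None, **overrides) -> dict:
    """Flat key-value configuration; unknown keys are rejected."""
    config: dict = {}
    if path:
        import yaml

        with open(path) as fh:
            config.update(yaml.safe_load(fh) or {})
    config.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        raise InvalidInputError(f"unknown configuration keys: {sorted(unknown)}")
    return config


def _sim_config(config: Mapping) -> simulate.SimulationConfig:
    fields = set(simulate.SimulationConfig.__dataclass_fields__)
    kwargs = {k: v for k, v in config.items() if k in fields}
    cfg = simulate.SimulationConfig(**kwargs)
    cfg.validate()
    return cfg


def _family_seed(seed: int, group: int, attempt: int = 0) -> int:
    return (seed * 100003 + group * 131 + attempt * 50021) % (2**31)


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(cfg: simulate.SimulationConfig, outdir: str) -> dict:
    os.makedirs(os.path.join(outdir, "pdb"), exist_ok=True)
    species = simulate.simulate_species_tree(
        cfg.n_taxa, cfg.birth_rate, seed=cfg.seed, root_age=cfg.root_age
    )
    trees.write_newick(species, os.path.join(outdir, "species_tree.nwk"))

    presence: dict[str, dict[str, int]] = {}
    taxa = [lf.taxon.label for lf in species.leaf_node_iter()]
    n_families = 0
    for g in range(1, cfg.n_groups + 1):
        gene_tree = truth = None
        for attempt in range(25):
            try:
                gene_tree, truth = simulate.simulate_gene_family(
                    species, cfg.dup_rate, cfg.loss_rate, seed=_family_seed(cfg.seed, g, attempt)
                )
                break
            except EmptyFamilyError:
                continue
        if gene_tree is None:
            raise EmptyFamilyError(f"family G{g}: no surviving copies after 25 attempts")
        trees.write_newick(gene_tree, os.path.join(outdir, f"gene_tree_G{g}.nwk"))
        truth.to_json(os.path.join(outdir, f"truth_family_G{g}.json"))
        with_copies = {lbl.split("|")[0] for lbl in trees.leaf_labels(gene_tree)}
        presence[f"G{g}"] = {t: int(t in with_copies) for t in taxa}
        n_families += 1

    chars = ancestral.CharacterMatrix(
        pd.DataFrame(presence, index=pd.Index(sorted(taxa), name="taxon")).astype(str)
    )
    chars.to_tsv(os.path.join(outdir, "characters.tsv"))

    records, ptruth = simulate.simulate_septin_proteome(cfg, seed=cfg.seed + 1)
    groups = {
        pid: f"G{(i % cfg.n_groups) + 1}"
        for i, pid in enumerate(ptruth.true_septin_ids)
    }
    simulate.write_proteome(
        records,
        ptruth,
        os.path.join(outdir, "proteome.fasta"),
        os.path.join(outdir, "annotations.tsv"),
        groups=groups,
    )
    ptruth.to_json(os.path.join(outdir, "truth_proteome.json"))

    structures, struth = simulate.simulate_dimer_structures(cfg, seed=cfg.seed + 2)
    with open(os.path.join(outdir, "manifest.tsv"), "w") as fh:
        fh.write("file\ttaxon\ttemplate_label\n")
        for s in structures:
            pdb_path = os.path.join("pdb", f"{s.id}.pdb")
            contacts.write_pdb(s, os.path.join(outdir, pdb_path))
            fh.write(f"{pdb_path}\t{s.taxon}\t{s.template}\n")
    struth.to_json(os.path.join(outdir, "truth_structures.json"))
    return {
        "n_taxa": cfg.n_taxa,
        "n_families": n_families,
        "n_proteins": len(records),
        "n_structures": len(structures),
    }


def stage_filter(outdir: str) -> dict:
    records = identify.read_proteome(
        os.path.join(outdir, "proteome.fasta"), os.path.join(outdir, "annotations.tsv")
    )
    retained, decisions = identify.filter_proteome(records)
    identify.write_fasta(retained, os.path.join(outdir, "retained.fasta"))
    identify.write_decisions(decisions, os.path.join(outdir, "decisions.tsv"))

    truth_path = os.path.join(outdir, "truth_proteome.json")
    counts = {"n_input": len(records), "n_retained": len(retained)}
    if os.path.exists(truth_path):
        with open(truth_path) as fh:
            true_ids = set(json.load(fh)["true_septin_ids"])
        kept = {r.id for r in retained}
        tp = len(kept & true_ids)
        counts["filter_precision"] = tp / len(kept) if kept else float("nan")
        counts["filter_recall"] = tp / len(true_ids) if true_ids else float("nan")
    return counts


def stage_groups(outdir: str) -> dict:
    n_assigned = 0
    for path in sorted(glob.glob(os.path.join(outdir, "gene_tree_G*.nwk"))):
        group = os.path.basename(path)[len("gene_tree_") : -len(".nwk")]
        tree = trees.read_newick(path)
        anchor = sorted(trees.leaf_labels(tree))[0]
        assignment = reconcile.assign_groups(tree, {anchor: group})
        out = os.path.join(outdir, f"groups_{group}.tsv")
        with open(out, "w") as fh:
            fh.write("leaf\tgroup\n")
            for leaf in sorted(assignment):
                fh.write(f"{leaf}\t{assignment[leaf]}\n")
        n_assigned += sum(1 for v in assignment.values() if v != reconcile.UNCLASSIFIED)
    return {"n_assigned_leaves": n_assigned}


def stage_reconcile(outdir: str, support_threshold: float = 0.90) -> dict:
    species = trees.read_newick(os.path.join(outdir, "species_tree.nwk"))
    total_dup = total_loss = 0.0
    summed_profile: dict[str, float] = {}
    for path in sorted(glob.glob(os.path.join(outdir, "gene_tree_G*.nwk"))):
        group = os.path.basename(path)[len("gene_tree_") : -len(".nwk")]
        gene_tree = trees.read_newick(path)
        results = reconcile.reconcile(
            gene_tree, species, support_threshold=support_threshold
        )
        total_dup += float(np.mean([r.n_duplications for r in results]))
        total_loss += float(np.mean([r.n_losses for r in results]))
        profile = reconcile.copy_number_profile(results)
        for branch, copies in profile.items():
            summed_profile[branch] = summed_profile.get(branch, 0.0) + copies
        with open(os.path.join(outdir, f"events_{group}.tsv"), "w") as fh:
            fh.write("node\tevent\n")
            for node, event in sorted(results[0].event_map.items()):
                fh.write(f"{node}\t{event}\n")
        with open(os.path.join(outdir, f"copies_{group}.tsv"), "w") as fh:
            fh.write("branch\tmean_copies\n")
            for branch in sorted(profile):
                fh.write(f"{branch}\t{profile[branch]:.4f}\n")
        with open(os.path.join(outdir, f"losses_{group}.tsv"), "w") as fh:
            fh.write("branch\tcount\n")
            for branch, count in sorted(results[0].loss_branches.items()):
                fh.write(f"{branch}\t{count}\n")
    with open(os.path.join(outdir, "copy_number_total.tsv"), "w") as fh:
        fh.write("branch\tsummed_mean_copies\n")
        for branch in sorted(summed_profile):
            fh.write(f"{branch}\t{summed_profile[branch]:.4f}\n")
    return {"total_duplications": total_dup, "total_losses": total_loss}


def stage_asr(outdir: str) -> dict:
    species = trees.read_newick(os.path.join(outdir, "species_tree.nwk"))
    chars = ancestral.CharacterMatrix.from_tsv(os.path.join(outdir, "characters.tsv"))
    n_rejected = 0
    with open(os.path.join(outdir, "model_fits.tsv"), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["character", "model", "q01", "q10", "lnL", "LRT", "p"])
        for char in chars.characters:
            column = chars.column(char)
            mk1, ll1 = ancestral.fit_mk(species, column, "MK1")
            mk2, ll2 = ancestral.fit_mk(species, column, "MK2")
            stat, p = ancestral.wilks_test(ll1, max(ll1, ll2))
            n_rejected += int(p < 0.05)
            w.writerow([char, "MK1", f"{mk1.q01:.6g}", f"{mk1.q10:.6g}", f"{ll1:.6f}", "", ""])
            w.writerow(
                [char, "MK2", f"{mk2.q01:.6g}", f"{mk2.q10:.6g}", f"{ll2:.6f}",
                 f"{stat:.6f}", f"{p:.6f}"]
            )
            recs = ancestral.marginal_reconstruction(species, column, mk1)
            ancestral.write_reconstruction(recs, os.path.join(outdir, f"asr_{char}.tsv"))
    return {"n_characters": len(chars.characters), "n_mk1_rejected": n_rejected}


def stage_conserve(outdir: str, background: str = "blosum62") -> dict:
    aln = conservation.Alignment.from_fasta(os.path.join(outdir, "retained.fasta"))
    reference_id = sorted(aln.sequences)[0]
    profile = conservation.conservation_profile(aln, background=background)
    ref_map = conservation.map_to_reference(aln, reference_id)
    conservation.write_profile(profile, ref_map, os.path.join(outdir, "conservation.tsv"))
    return {
        "reference_id": reference_id,
        "n_columns": aln.length,
        "n_high_conservation": int((profile.scores > 0.5).sum()),
        "max_conservation": float(profile.scores.max()),
    }


def stage_contacts(
    outdir: str, probe_diameter: float = 0.5, min_taxa: int = 10
) -> dict:
    manifest = pd.read_csv(os.path.join(outdir, "manifest.tsv"), sep="\t")
    residue_sets = {}
    taxa = set()
    with open(os.path.join(outdir, "contacts.tsv"), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["taxon", "template", "chain_a", "res_a", "chain_b", "res_b", "min_gap"])
        for row in manifest.itertuples():
            structure = contacts.read_pdb(
                os.path.join(outdir, row.file),
                structure_id=os.path.basename(row.file),
                taxon=row.taxon,
                template=row.template_label,
            )
            found = contacts.detect_contacts(structure, probe_diameter)
            for c in found:
                w.writerow(
                    [row.taxon, row.template_label, c.residue_a[0], c.residue_a[1],
                     c.residue_b[0], c.residue_b[1], f"{c.min_gap:.3f}"]
                )
            residue_sets[(row.taxon, row.template_label)] = contacts.residue_interface_set(found)
            taxa.add(row.taxon)
    consensus = contacts.aggregate_interfaces(
        residue_sets, n_taxa=len(taxa), min_taxa=min_taxa
    )
    contacts.write_consensus(consensus, os.path.join(outdir, "consensus.tsv"))
    by_interface = {"G": [], "NC": []}
    for c in consensus:
        if c.consensus:
            by_interface[c.interface].append(c.position)
    with open(os.path.join(outdir, "interface_groups.tsv"), "w") as fh:
        fh.write("interface\tig_index\tstart\tend\n")
        for interface in ("G", "NC"):
            for i, (start, end) in enumerate(
                contacts.interface_cluster(by_interface[interface]), start=1
            ):
                fh.write(f"{interface}\t{i}\t{start}\t{end}\n")

    counts = {
        "n_consensus_G": len(by_interface["G"]),
        "n_consensus_NC": len(by_interface["NC"]),
    }

    # per-Group logo matrices over the consensus positions
    retained_path = os.path.join(outdir, "retained.fasta")
    ann_path = os.path.join(outdir, "annotations.tsv")
    if os.path.exists(retained_path) and os.path.exists(ann_path):
        aln = conservation.Alignment.from_fasta(retained_path)
        ann = pd.read_csv(ann_path, sep="\t").fillna("")
        group_of = {
            r.protein_id: r.group
            for r in ann.itertuples()
            if r.group and r.protein_id in aln.sequences
        }
        reference_id = sorted(aln.sequences)[0]
        ref_map = conservation.map_to_reference(aln, reference_id)
        positions = [
            p for p in by_interface["G"] + by_interface["NC"]
            if p in ref_map.residue_to_column
        ]
        profiles = contacts.group_frequency_profiles(aln, group_of, positions, ref_map)
        for group, frame in profiles.items():
            frame.round(6).to_csv(
                os.path.join(outdir, f"logo_{group}.tsv"), sep="\t"
            )
        counts["n_logo_groups"] = len(profiles)
    return counts


# ---------------------------------------------------------------------------
# Orchestration

def run_pipeline(config: Mapping) -> dict:
    """Run the enabled stages in dependency order and write the run report.

    Returns the report dictionary (also written to ``report.json`` without
    timings, and ``report.txt`` with them).
    """
    config = dict(config)
    outdir = config.get("outdir", "septevo_out")
    stages = tuple(config.get("stages", STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise InvalidInputError(f"unknown stages: {sorted(unknown)}")
    os.makedirs(outdir, exist_ok=True)

    cfg = _sim_config(config)
    if "simulate" not in stages:
        required = {
            "filter": ["proteome.fasta", "annotations.tsv"],
            "groups": ["gene_tree_G1.nwk"],
            "reconcile": ["species_tree.nwk", "gene_tree_G1.nwk"],
            "asr": ["species_tree.nwk", "characters.tsv"],
            "conserve": ["retained.fasta"],
            "contacts": ["manifest.tsv"],
        }
        missing = [
            f
            for stage in stages
            for f in required.get(stage, [])
            if not os.path.exists(os.path.join(outdir, f))
        ]
        if missing:
            raise InvalidInputError(f"missing inputs for requested stages: {missing}")

    report: dict = {
        "parameters": {k: v for k, v in sorted(asdict(cfg).items()) if k != "contact_dropout"},
        "stages": {},
    }
    timings: dict[str, float] = {}
    runners = {
        "simulate": lambda: stage_simulate(cfg, outdir),
        "filter": lambda: stage_filter(outdir),
        "groups": lambda: stage_groups(outdir),
        "reconcile": lambda: stage_reconcile(
            outdir, float(config.get("support_threshold", 0.90))
        ),
        "asr": lambda: stage_asr(outdir),
        "conserve": lambda: stage_conserve(outdir, config.get("background", "blosum62")),
        "contacts": lambda: stage_contacts(
            outdir,
            float(config.get("probe_diameter", 0.5)),
            int(config.get("min_taxa", 10)),
        ),
    }
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("stage %s: starting", stage)
        t0 = time.perf_counter()
        try:
            report["stages"][stage] = runners[stage]()
        except Exception:
            with open(os.path.join(outdir, "FAILED"), "w") as fh:
                fh.write(f"stage {stage} failed\n")
            log.exception("stage %s failed", stage)
            raise
        timings[stage] = time.perf_counter() - t0
        log.info("stage %s: done in %.2fs", stage, timings[stage])

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(outdir, "report.txt"), "w") as fh:
        fh.write("septevo run report\n==================\n")
        for stage, counts in report["stages"].items():
            fh.write(f"\n[{stage}] ({timings[stage]:.2f}s)\n")
            for k, v in counts.items():
                fh.write(f"  {k}: {v}\n")
    return report
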