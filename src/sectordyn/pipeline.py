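"""Full analysis orchestration: process MSA → SCA → DCC → compare → motifs.

A single :class:`PipelineConfig` (loadable from YAML) drives the chain and
every stage writes plain-text artifacts (TSV/JSON/FASTA) into the output
directory, together with a manifest (config echo, seeds, input checksums,
package version, interpretation notes) sufficient to reproduce the run.
Stages are resumable: when a stage's outputs already exist under an
unchanged manifest the cached files are reused.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import (
    InsertionSpec,
    categorize_pairs,
    category_distributions,
    compare_between_conditions,
    compare_within_condition,
    renumber_dcc,
    write_pair_table,
    write_report,
)
from .motifs import PatternSpec, cooccurrence, count_pattern, write_contingency
from .msa_io import (
    ProcessingParams,
    process_msa,
    read_alignment,
    write_alignment,
    write_position_map,
)
from .sca import (
    BACKGROUND_DB,
    BACKGROUND_UNIFORM,
    assign_ic_positions,
    build_sca_matrix,
    compute_frequencies,
    compute_sequence_weights,
    eigendecompose,
    order_matrix_by_ic,
    positional_conservation,
    rotate_ica,
    select_significant_eigenmodes,
)
from .trajectory import (
    compute_dcc,
    read_trajectory,
    superpose_trajectory,
    write_dcc,
)

log = logging.getLogger("sectordyn")

INTERPRETATION_NOTES = [
    "Insertion renumbering applies the offset to residues >= insertion_after "
    "(site 23 with offset +1 maps residue 23 to 24).",
    "Pair separation is computed on reference residue numbering after "
    "insertion renumbering; pairs with separation <= min_separation are "
    "excluded (default 2: residues 50 and 52 are dropped, 50 and 53 kept).",
    "Mann-Whitney p-values are reported raw; the Holm column is informational.",
]


@dataclass
class ConditionConfig:
    """One trajectory condition (e.g. wild type or mutant)."""

    name: str
    trajectory: str
    trajectory_format: str = "frame-table"
    selection: str | None = "CA"
    insertion_after: int | None = None
    insertion_offset: int = 1
    frame_range: tuple[int, int] | None = None


@dataclass
class PipelineConfig:
    msa_path: str = ""
    msa_format: str = "fasta"
    reference_id: str = ""
    first_residue_number: int = 1
    output_dir: str = "pipeline_out"
    conditions: list[ConditionConfig] = field(default_factory=list)
    # processing
    max_col_gap_fraction: float = 0.4
    max_seq_gap_fraction: float = 0.2
    min_ref_identity: float = 0.2
    # SCA
    identity_cutoff: float = 0.8
    pseudocount: float = 0.03
    n_trials: int = 10
    seed: int = 0
    p_cutoff: float = 0.95
    background: str = "uniform"  # or "database"
    # comparison
    min_separation: int = 2
    # motifs: list of (name, pattern_a triples, pattern_b triples or None)
    motif_patterns: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        conds = [ConditionConfig(**c) for c in raw.pop("conditions", [])]
        cfg = cls(**raw, conditions=conds)
        return cfg

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["conditions"] = [dict(c.__dict__) for c in self.conditions]
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict.

    Raises with the failing stage's name; a partial manifest of completed
    stages is written beforehand so reruns resume from cached artifacts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest: dict = {
        "version": __version__,
        # round-trip through JSON so tuples normalise to lists and the echo
        # compares cleanly against a reloaded manifest
        "config": json.loads(json.dumps(config.to_dict())),
        "interpretation_notes": INTERPRETATION_NOTES,
        "inputs": {},
        "stages": {},
    }

    msa_path = Path(config.msa_path)
    if not msa_path.exists():
        raise FileNotFoundError(f"stage process-msa: MSA not found: {msa_path}")
    manifest["inputs"][str(msa_path)] = _sha256(msa_path)
    for cond in config.conditions:
        tp = Path(cond.trajectory)
        if not tp.exists():
            raise FileNotFoundError(
                f"stage dcc: condition {cond.name!r}: trajectory not found: {tp}"
            )
        manifest["inputs"][str(tp)] = _sha256(tp)

    cached = None
    if manifest_path.exists():
        with open(manifest_path) as fh:
            cached = json.load(fh)
        if (
            cached.get("config") != manifest["config"]
            or cached.get("inputs") != manifest["inputs"]
        ):
            cached = None

    def _save_manifest() -> None:
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    def _stage_done(name: str, files: list[Path]) -> bool:
        return (
            cached is not None
            and name in cached.get("stages", {})
            and all(f.exists() for f in files)
        )

    # ---------------- stage: process-msa ----------------
    stage = "process-msa"
    msa_out = out / "processed_msa.fasta"
    pmap_out = out / "position_map.tsv"
    reference_id = config.reference_id
    if _stage_done(stage, [msa_out, pmap_out]):
        log.info("%s: reusing cached artifacts", stage)
        from .msa_io import ProcessedAlignment, read_position_map

        processed = ProcessedAlignment(
            read_alignment(msa_out, "fasta"),
            read_position_map(pmap_out, reference_id),
            cached["stages"][stage]["filter_log"],
        )
        manifest["stages"][stage] = cached["stages"][stage]
    else:
        aln = read_alignment(msa_path, config.msa_format)
        params = ProcessingParams(
            config.max_col_gap_fraction,
            config.max_seq_gap_fraction,
            config.min_ref_identity,
        )
        reference_id = reference_id or aln.seq_ids[0]
        processed = process_msa(
            aln, reference_id, params, config.first_residue_number
        )
        log.info("%s: filter log %s", stage, processed.filter_log)
        write_alignment(processed.alignment, msa_out)
        write_position_map(processed.position_map, pmap_out)
        manifest["stages"][stage] = {"filter_log": processed.filter_log}
    _save_manifest()
    resnums = processed.position_map.residue_numbers

    # ---------------- stage: sca ----------------
    stage = "sca"
    sca_files = [
        out / "sca_matrix.tsv", out / "ic_loadings.tsv",
        out / "ic_membership.tsv", out / "sca_matrix_ic_ordered.tsv",
    ]
    if _stage_done(stage, sca_files):
        log.info("%s: reusing cached artifacts", stage)
        from .sca import ICAssignment, SCAMatrix

        sca = SCAMatrix(
            pd.read_csv(sca_files[0], sep="\t", index_col=0).to_numpy()
        )
        load_df = pd.read_csv(sca_files[1], sep="\t", index_col=0)
        mem_df = pd.read_csv(sca_files[2], sep="\t")
        k_star = load_df.shape[1]
        memberships = [
            sorted(mem_df.loc[mem_df["ic_id"] == k, "ref_residue_number"])
            for k in range(1, k_star + 1)
        ]
        ics = ICAssignment(
            ic_vectors=load_df.to_numpy(),
            memberships=memberships,
            p_cutoff=config.p_cutoff,
            fit_params=[None] * k_star,
            loadings_cdf=np.zeros_like(load_df.to_numpy()),
        )
        manifest["stages"][stage] = cached["stages"][stage]
    else:
        background = (
            BACKGROUND_UNIFORM if config.background == "uniform" else BACKGROUND_DB
        )
        weights = compute_sequence_weights(processed, config.identity_cutoff)
        log.info("%s: m_eff = %.1f", stage, weights.m_eff)
        freqs = compute_frequencies(processed, weights, config.pseudocount)
        cons = positional_conservation(freqs, background)
        sca = build_sca_matrix(freqs, cons)
        k_star = select_significant_eigenmodes(
            sca, processed, weights,
            n_trials=config.n_trials, seed=config.seed,
            pseudocount=config.pseudocount, background=background,
        )
        log.info("%s: %d significant eigenmodes", stage, k_star)
        pd.DataFrame(sca.c, index=resnums, columns=resnums).to_csv(
            out / "sca_matrix.tsv", sep="\t", index_label="residue"
        )
        if k_star == 0:
            manifest["stages"][stage] = {
                "m_eff": weights.m_eff, "k_star": 0,
                "note": "no significant modes",
            }
            _save_manifest()
            raise RuntimeError(
                "stage sca: no significant eigenmodes; downstream stages skipped"
            )
        _, vecs = eigendecompose(sca)
        ica = rotate_ica(vecs[:, :k_star], seed=config.seed)
        ics = assign_ic_positions(
            ica.ic_vectors, config.p_cutoff, processed.position_map
        )
        loadings = pd.DataFrame(
            ics.ic_vectors,
            index=resnums,
            columns=[f"IC{k+1}" for k in range(ics.n_ics)],
        )
        loadings.to_csv(out / "ic_loadings.tsv", sep="\t", index_label="residue")
        rows = []
        for k, members in enumerate(ics.memberships, start=1):
            for res in members:
                i = int(np.flatnonzero(resnums == res)[0])
                rows.append(
                    {
                        "ic_id": k,
                        "ref_residue_number": res,
                        "loading": ics.ic_vectors[i, k - 1],
                        "cdf": ics.loadings_cdf[i, k - 1],
                    }
                )
        pd.DataFrame(
            rows, columns=["ic_id", "ref_residue_number", "loading", "cdf"]
        ).to_csv(out / "ic_membership.tsv", sep="\t", index=False)
        ordered, perm = order_matrix_by_ic(sca, ics, processed.position_map)
        ord_res = resnums[perm]
        pd.DataFrame(ordered, index=ord_res, columns=ord_res).to_csv(
            out / "sca_matrix_ic_ordered.tsv", sep="\t", index_label="residue"
        )
        np.savetxt(out / "ic_order_permutation.tsv", perm, fmt="%d")
        manifest["stages"][stage] = {
            "m_eff": weights.m_eff,
            "k_star": k_star,
            "ic_sizes": [len(m) for m in ics.memberships],
            "ica_converged": ica.converged,
        }
    _save_manifest()

    # ---------------- stage: dcc + compare per condition ----------------
    dists_by_cond: dict[str, dict[str, np.ndarray]] = {}
    for cond in config.conditions:
        stage = f"dcc[{cond.name}]"
        dcc_out = out / f"dcc_{cond.name}.tsv"
        if _stage_done(stage, [dcc_out]):
            log.info("%s: reusing cached artifacts", stage)
            from .trajectory import read_dcc

            dcc = read_dcc(dcc_out)
            manifest["stages"][stage] = cached["stages"][stage]
        else:
            traj = read_trajectory(
                cond.trajectory, cond.trajectory_format, cond.selection
            )
            traj = superpose_trajectory(traj, "mean_structure")
            dcc = compute_dcc(traj, cond.frame_range)
            if cond.insertion_after is not None:
                dcc = renumber_dcc(
                    dcc,
                    InsertionSpec(cond.insertion_after, cond.insertion_offset),
                )
            write_dcc(dcc, dcc_out)
            manifest["stages"][stage] = {"n_frames": traj.n_frames}
        pairs = categorize_pairs(dcc, ics, config.min_separation)
        write_pair_table(pairs, out / f"pairs_{cond.name}.tsv")
        dists = category_distributions(pairs, n_ics=ics.n_ics)
        dists_by_cond[cond.name] = dists
        report = compare_within_condition(dists)
        write_report(report, out / f"within_{cond.name}.tsv")
        manifest["stages"][stage]["n_pairs_retained"] = int(len(pairs))
        _save_manifest()

    if len(config.conditions) >= 2:
        stage = "compare-between"
        names = [c.name for c in config.conditions]
        for a_idx in range(len(names)):
            for b_idx in range(a_idx + 1, len(names)):
                a, b = names[a_idx], names[b_idx]
                rep = compare_between_conditions(
                    dists_by_cond[a], dists_by_cond[b], a, b
                )
                write_report(rep, out / f"between_{a}_vs_{b}.tsv")
        manifest["stages"][stage] = {"pairs": "all condition pairs"}
        _save_manifest()

    # ---------------- stage: motifs ----------------
    if config.motif_patterns:
        stage = "motif"
        rows = []
        for entry in config.motif_patterns:
            name = entry["name"]
            pat_a = PatternSpec.from_triples(entry["pattern"])
            count = count_pattern(processed, pat_a)
            rows.append({"name": name, "count": count})
            if entry.get("against"):
                pat_b = PatternSpec.from_triples(entry["against"])
                table = cooccurrence(processed, pat_a, pat_b)
                write_contingency(
                    table, out / f"cooccurrence_{name}.tsv", name, "against"
                )
        pd.DataFrame(rows).to_csv(
            out / "motif_counts.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = {"n_patterns": len(config.motif_patterns)}
        _save_manifest()

    _save_manifest()
    return manifest
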