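"""End-to-end orchestration: simulate -> detect -> curate -> analyse.

``run_all`` drives the whole workflow from a single JSON-able configuration
with per-stage RNG streams derived from one master seed, writes every
stage's outputs (FASTA, GFF3, TSV tables) plus a summary JSON, and records
a manifest with the configuration hash and per-stage counts so a rerun with
the same manifest reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .curate import annotate_elements, curate, rt_validator
from .dating import DEFAULT_MU, compare_age_groups, estimate_age, identity_delta
from .detect import DetectionParams, recursive_detect
from .io import write_fasta, write_gff3
from .models import COPIA, GYPSY, SimConfig
from .motifs import build_logo_data, gc_compare, tsd_length_distribution
from .nucleosome import (
    NucleosomeModelParams,
    average_profile,
    element_body_profile,
    element_site_windows,
)
from .palindromes import element_site_window, paired_shuffle_test
from .regions import (
    assign_region,
    autoinsertion_matrix,
    recent_old_split,
    region_preference_table,
    schema_from_elements,
    superfamily_enrichment,
)
from .simulate import build_family_panel, plant_genome

logger = logging.getLogger(__name__)

_DEFAULTS: dict = {
    "seed": 7,
    "mu": DEFAULT_MU,
    "simulate": {},
    "detect": {},
    "palindrome": {"max_error_rate": 1.0 / 3.0, "min_stem": 3},
    "nucleosome": {"amplitude": 0.2, "period": 10.1, "footprint": 147,
                   "window": 1124},
}


def validate_config(config: dict | str | Path) -> dict:
    """Normalize a pipeline configuration: schema check, defaults, and
    rejection of unknown keys with per-field messages."""
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    if not isinstance(config, dict):
        raise ValueError("configuration must be a JSON object")
    unknown = set(config) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown configuration sections: {sorted(unknown)}")
    cfg = json.loads(json.dumps(_DEFAULTS))  # deep copy
    for key, value in config.items():
        if isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    if not isinstance(cfg["seed"], int):
        raise ValueError("seed must be an integer")
    if cfg["mu"] <= 0:
        raise ValueError("mu must be > 0")
    sim = dict(cfg["simulate"])
    sim.setdefault("rng_seed", cfg["seed"])
    sim.setdefault("mutation_rate_mu", cfg["mu"])
    SimConfig.from_dict(sim)  # raises with a per-field message
    cfg["simulate"] = sim
    known_detect = {f.name for f in dataclasses.fields(DetectionParams)}
    bad = set(cfg["detect"]) - known_detect
    if bad:
        raise ValueError(f"unknown detect keys: {sorted(bad)}")
    if not 0 < cfg["palindrome"]["max_error_rate"] < 1:
        raise ValueError("palindrome.max_error_rate must be in (0,1)")
    return cfg


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _profile_frame(profile) -> pd.DataFrame:
    return pd.DataFrame({
        "position": profile.positions,
        "mean_occupancy": profile.mean_occupancy,
        "n": profile.n_sequences,
    })


def run_all(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run the full pipeline; returns the summary dict (also written as
    summary.json). Partial outputs are kept on failure, with the manifest
    noting the failed stage."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _hash_config(cfg),
        "config": cfg,
        "package_version": __version__,
        "stages": {},
        "failed_stage": None,
    }
    summary: dict = {}
    ss = np.random.SeedSequence(cfg["seed"])
    pal_rng, nuc_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    try:
        _run_stages(cfg, out, manifest, summary, pal_rng, nuc_rng)
    except Exception as exc:  # keep partial outputs + note the failure point
        manifest["failed_stage"] = manifest.get("current_stage")
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise
    manifest.pop("current_stage", None)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True, default=str))
    return summary


def _run_stages(cfg, out, manifest, summary, pal_rng, nuc_rng) -> None:
    mu = cfg["mu"]
    pal_cfg = cfg["palindrome"]
    nuc_cfg = cfg["nucleosome"]
    nuc_params = NucleosomeModelParams(
        footprint=nuc_cfg["footprint"], period=nuc_cfg["period"],
        amplitude=nuc_cfg["amplitude"],
    )

    # ------------------------------------------------------------ simulate
    manifest["current_stage"] = "simulate"
    sim_cfg = SimConfig.from_dict(cfg["simulate"])
    panel = build_family_panel(sim_cfg.panel_seed, element_gc=sim_cfg.element_gc)
    genome, truth = plant_genome(sim_cfg, panel=panel)
    write_fasta(out / "genome.fasta", {truth.genome_id: genome})
    write_gff3(out / "truth.gff3", truth.elements)
    manifest["stages"]["simulate"] = {
        "genome_length": len(genome),
        "n_elements": len(truth.elements),
        "n_true_pairs": len(truth.pairs),
    }

    # -------------------------------------------------------------- detect
    manifest["current_stage"] = "detect"
    det_params = DetectionParams(**cfg["detect"])
    candidates = recursive_detect(genome, det_params, genome_id=truth.genome_id,
                                  validator=rt_validator(panel))
    manifest["stages"]["detect"] = {"n_candidates": len(candidates)}

    # -------------------------------------------------------------- curate
    manifest["current_stage"] = "curate"
    elements = annotate_elements(candidates, panel, genome=genome)
    cur = curate(elements, genome)
    write_gff3(out / "detected.gff3", cur.elements)
    manifest["stages"]["curate"] = dict(cur.attrition)
    by_id = {el.id: el for el in cur.elements}

    # recovery vs planted truth (ground-truth mode)
    matched = 0
    for el in truth.elements:
        if any(abs(d.start - el.start) <= 2 and abs(d.end - el.end) <= 2
               for d in cur.elements):
            matched += 1
    recovery = 100.0 * matched / max(1, len(truth.elements))
    summary["recovery"] = {
        "planted": len(truth.elements),
        "recovered": matched,
        "recovery_pct": recovery,
    }

    # ---------------------------------------------------------------- date
    manifest["current_stage"] = "date"
    ages = {}
    for el in cur.elements:
        try:
            ages[el.id] = estimate_age(el, mu=mu)
        except ValueError:
            logger.info("element %s not datable", el.id)
    for pair in cur.pairs:
        identity_delta(pair, ages)
    date_rows = [
        {"element_id": a.element_id, "ltr_identity_pct": a.ltr_identity_pct,
         "divergence": a.divergence, "insertion_time_mya": a.insertion_time_mya}
        for a in ages.values()
    ]
    pd.DataFrame(date_rows).sort_values("element_id").to_csv(
        out / "dating.tsv", sep="\t", index=False)
    nested_ages = [ages[p.nested_id].insertion_time_mya for p in cur.pairs
                   if p.nested_id in ages]
    original_ages = [ages[p.original_id].insertion_time_mya for p in cur.pairs
                     if p.original_id in ages]
    if len(nested_ages) >= 2 and len(original_ages) >= 2:
        summary["age_comparison"] = compare_age_groups(nested_ages, original_ages)

    # ------------------------------------------------------------- regions
    manifest["current_stage"] = "regions"
    for pair in cur.pairs:
        original = by_id.get(pair.original_id)
        if original is not None and original.regions:
            assign_region(pair, original)
    pair_rows = [dataclasses.asdict(p) for p in cur.pairs]
    pd.DataFrame(pair_rows).to_csv(out / "pairs.tsv", sep="\t", index=False)

    region_tables = {}
    for sf in (GYPSY, COPIA):
        schema = schema_from_elements(cur.elements, sf)
        if not schema.family_lengths:
            continue
        tab = region_preference_table(cur.pairs, by_id, schema)
        if tab is None:
            continue
        tab.table.to_csv(out / f"region_preference_{sf}.tsv", sep="\t")
        region_tables[sf] = {
            "chi2": tab.chi2, "df": tab.df, "p_global": tab.p_global,
            "significant_regions": tab.table.index[tab.table.significant].tolist(),
        }
        recent, old = recent_old_split(cur.pairs)
        for label, subset in (("recent", recent), ("old", old)):
            sub_tab = region_preference_table(subset, by_id, schema)
            if sub_tab is not None:
                sub_tab.table.to_csv(
                    out / f"region_preference_{sf}_{label}.tsv", sep="\t")
    summary["region_preference"] = region_tables

    matrix, fractions = autoinsertion_matrix(cur.pairs)
    if not matrix.empty:
        matrix.to_csv(out / "autoinsertion_matrix.tsv", sep="\t")
        summary["autoinsertion_fractions"] = {
            str(k): float(v) for k, v in fractions.items()}

    nested_sf = (
        sum(1 for p in cur.pairs if by_id[p.nested_id].superfamily == GYPSY),
        sum(1 for p in cur.pairs if by_id[p.nested_id].superfamily == COPIA),
    )
    nn_sf = (
        sum(1 for el in cur.non_nested if el.superfamily == GYPSY),
        sum(1 for el in cur.non_nested if el.superfamily == COPIA),
    )
    if min(nested_sf) + min(nn_sf) > 0 and sum(nested_sf) and sum(nn_sf):
        try:
            summary["superfamily_enrichment"] = superfamily_enrichment(
                nested_sf, nn_sf)
        except ValueError:
            pass
    summary["counts"] = {
        "pairs_curated": len(cur.pairs),
        "pairs_motif": len(cur.pairs_motif),
        "non_nested": len(cur.non_nested),
        "nested_by_superfamily": list(nested_sf),
        "non_nested_by_superfamily": list(nn_sf),
    }

    # ---------------------------------------------------------------- tsd
    manifest["current_stage"] = "tsd"
    motif_elements = sorted(
        {p.nested_id for p in cur.pairs_motif} | {el.id for el in cur.non_nested})
    records = [by_id[i].tsd for i in motif_elements if by_id[i].tsd is not None]
    logos = build_logo_data(records)
    for k, pfm in logos.items():
        frame = pfm.counts.copy()
        frame["information_bits"] = pfm.information
        frame.to_csv(out / f"tsd_logo_k{k}.tsv", sep="\t")
    families = {el.id: el.family for el in cur.elements}
    per_family, per_k = tsd_length_distribution(records, families)
    if not per_family.empty:
        per_family.to_csv(out / "tsd_length_by_family.tsv", sep="\t")
        per_k.to_csv(out / "tsd_family_by_length.tsv", sep="\t")
    el_seqs = [el.seq for el in cur.elements if el.seq]
    if el_seqs:
        summary["gc"] = gc_compare(el_seqs, genome)

    # ----------------------------------------------------------- palindrome
    manifest["current_stage"] = "palindrome"
    groups: dict[str, list[str]] = {"nested": [], "non-nested": []}
    for el_id in motif_elements:
        el = by_id[el_id]
        window = element_site_window(genome, el, half=10)
        if window is None:
            continue
        key = "nested" if el.parent_id is not None else "non-nested"
        groups[key].append(window)
        groups.setdefault(el.family, []).append(window)
    groups["ALL"] = groups["nested"] + groups["non-nested"]
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if "ALL" in groups:
        results = paired_shuffle_test(
            groups, pal_rng, min_stem=pal_cfg["min_stem"],
            max_error_rate=pal_cfg["max_error_rate"])
        frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
        frame.to_csv(out / "palindrome_summary.tsv", sep="\t", index=False)
        summary["palindrome"] = {
            r.group: {"n": r.n, "mean_native": r.mean_native,
                      "mean_random": r.mean_random, "p": r.paired_t_p,
                      "p_adj": r.p_adj}
            for r in results if r.group in ("ALL", "nested", "non-nested")
        }

    # ----------------------------------------------------------- nucleosome
    manifest["current_stage"] = "nucleosome"
    site_elements = [by_id[i] for i in motif_elements]
    windows = element_site_windows(genome, site_elements,
                                   window=nuc_cfg["window"])
    if windows:
        native = average_profile(windows, nuc_params)
        control = average_profile(windows, nuc_params, shuffled_control=True,
                                  rng=nuc_rng)
        nat = _profile_frame(native)
        nat["control"] = _profile_frame(control)["mean_occupancy"]
        nat.to_csv(out / "nucleosome_profile.tsv", sep="\t", index=False)
        center = np.abs(native.positions) <= 75
        # interior positions exclude the footprint-wide coverage ramps at the
        # window edges, which would otherwise bias the window-wide mean low
        interior = (np.arange(native.positions.size) >= nuc_params.footprint) & \
            (np.arange(native.positions.size) < native.positions.size - nuc_params.footprint)
        summary["nucleosome"] = {
            "n_windows": native.n_sequences,
            "central_mean": float(native.mean_occupancy[center].mean()),
            "interior_mean": float(native.mean_occupancy[interior].mean()),
            "control_central_mean": float(control.mean_occupancy[center].mean()),
            "control_interior_mean": float(control.mean_occupancy[interior].mean()),
        }
    for sf in (GYPSY, COPIA):
        els = [el for el in cur.elements if el.superfamily == sf and el.seq]
        if els:
            prof = element_body_profile(els, nuc_params)
            _profile_frame(prof).to_csv(out / f"body_profile_{sf}.tsv",
                                        sep="\t", index=False)
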