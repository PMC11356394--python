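"""End-to-end orchestration of the analysis stages from one configuration file.

A run harmonizes the alignment, classifies haplotypes into haplogroups,
computes diversity summaries, fits the demographic-expansion statistics per
haplogroup, runs the configured AMOVA designs, builds the median-joining
network with regional projections, and writes everything as TSV reports plus
a machine-readable manifest (seeds, parameters, stage timings) sufficient to
reproduce the run.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .alignment import (WINDOW_END, WINDOW_START, harmonize, read_alignment,
                        site_summary, write_alignment)
from .amova import Amova, AmovaDesign
from .demography import (SuddenExpansionModel, expansion_time, fus_fs,
                         mismatch_distribution)
from .diversity import diversity_table, summarize_groups
from .errors import ConfigurationError
from .haplotypes import (HaplotypeTable, MotifSet, classify_table,
                         collapse_haplotypes, expand_to_samples,
                         name_haplotypes, pairwise_distance_matrix,
                         read_weights_tsv)
from .network import build_mjn, export_network, regional_projection


@dataclass(frozen=True)
class RunConfig:
    alignment: Path
    metadata: Path
    motifs: Path
    outdir: Path
    weights: Path | None = None
    window_start: int = WINDOW_START
    window_end: int = WINDOW_END
    group_by: str = "region"
    mu_site_year: float = 6.13e-8
    gen_years: float = 8.0
    n_boot: int = 200
    n_perm: int = 999
    n_sim_fs: int = 500
    seed: int = 1
    epsilon: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError("run config must be a mapping")
        kwargs = {}
        for key in ("alignment", "metadata", "motifs", "weights", "outdir"):
            if key in raw:
                kwargs[key] = Path(raw.pop(key))
        kwargs.update(raw)
        missing = {"alignment", "metadata", "motifs", "outdir"} - set(kwargs)
        if missing:
            raise ConfigurationError(f"run config missing keys: {sorted(missing)}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in ("alignment", "metadata", "motifs"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise ConfigurationError(f"{key} file not found: {p}")
        if self.weights is not None and not Path(self.weights).exists():
            raise ConfigurationError(f"weights file not found: {self.weights}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns the manifest dictionary."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "mitopop", "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "window": [cfg.window_start, cfg.window_end],
            "group_by": cfg.group_by, "mu_site_year": cfg.mu_site_year,
            "gen_years": cfg.gen_years, "n_boot": cfg.n_boot,
            "n_perm": cfg.n_perm, "n_sim_fs": cfg.n_sim_fs,
            "epsilon": cfg.epsilon,
        },
        "inputs": {
            "alignment": str(cfg.alignment), "metadata": str(cfg.metadata),
            "motifs": str(cfg.motifs),
            "weights": str(cfg.weights) if cfg.weights else None,
        },
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done():
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        return done

    # --- harmonize -------------------------------------------------------
    done = stage("harmonize")
    aln = read_alignment(cfg.alignment, cfg.metadata)
    aln = harmonize(aln, cfg.window_start, cfg.window_end)
    write_alignment(aln, out / "harmonized.fasta")
    sites = site_summary(aln)
    sites.to_frame().to_csv(out / "site_summary.tsv", sep="\t", index=False)
    done()

    # --- classify --------------------------------------------------------
    done = stage("classify")
    motifs = MotifSet.from_tsv(cfg.motifs)
    table = collapse_haplotypes(aln, group_by=cfg.group_by)
    assignments = classify_table(table, motifs)
    table, assignments = name_haplotypes(table, assignments)
    table.to_frame().to_csv(out / "haplotypes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(a.name, a.label) for a in assignments], columns=["name", "haplogroup"]
    ).to_csv(out / "haplogroups.tsv", sep="\t", index=False)
    done()

    # --- diversity -------------------------------------------------------
    done = stage("diversity")
    records = summarize_groups(table, assignments)
    diversity_table(records).to_csv(out / "diversity.tsv", sep="\t", index=False)
    done()

    # --- demography ------------------------------------------------------
    done = stage("demography")
    label_of = {a.name: a.label for a in assignments}
    demo_rows = []
    for hg in ("A", "B"):
        entries = tuple(e for e in table.entries if label_of[e.name] == hg)
        n = sum(e.total_count for e in entries)
        if n < 3 or len(entries) < 2:
            continue
        sub = HaplotypeTable(entries, n, table.groups, table.positions)
        obs = mismatch_distribution(sub)
        res = SuddenExpansionModel(obs).fit(n_boot=cfg.n_boot, seed=cfg.seed + ord(hg))
        L = len(table.positions)
        te = expansion_time(res.tau, cfg.mu_site_year, cfg.gen_years, L)
        iu_mean = obs.mean
        fs = fus_fs(n, len(entries), iu_mean, n_sim=cfg.n_sim_fs,
                    seed=cfg.seed + 100 + ord(hg))
        demo_rows.append({
            "haplogroup": hg, "N": n, "nh": len(entries),
            "tau": res.tau, "tau_low": res.tau_ci[0], "tau_high": res.tau_ci[1],
            "theta0": res.theta0, "SSD": res.ssd, "P_SSD": res.p_ssd,
            "HRI": res.hri, "P_HRI": res.p_hri,
            "Fs": fs.fs, "P_Fs": fs.p,
            "expansion_years": te.years,
        })
    pd.DataFrame(demo_rows).to_csv(out / "demography.tsv", sep="\t", index=False)
    done()

    # --- AMOVA -----------------------------------------------------------
    done = stage("amova")
    weights = read_weights_tsv(cfg.weights) if cfg.weights else None
    dist = pairwise_distance_matrix(table)
    d2 = expand_to_samples(table, dist)
    # sample-level labels in table expansion order
    groups, pops = [], []
    for e in table.entries:
        for g in sorted(e.group_counts):
            groups.extend([label_of[e.name]] * e.group_counts[g])
            pops.extend([g] * e.group_counts[g])
    designs = {
        "populations": AmovaDesign.one_level(pops, "populations"),
        "haplogroups_populations": AmovaDesign.two_level(
            groups, [f"{g}|{p}" for g, p in zip(groups, pops)],
            "haplogroups/populations-within"),
    }
    amova_frames = []
    for name, design in designs.items():
        res = Amova(d2, design).fit(n_perm=cfg.n_perm, seed=cfg.seed)
        frame = res.summary()
        frame.insert(0, "design", name)
        amova_frames.append(frame)
    pd.concat(amova_frames, ignore_index=True).to_csv(
        out / "amova.tsv", sep="\t", index=False)
    done()

    # --- network ---------------------------------------------------------
    done = stage("network")
    net = build_mjn(table, weights=weights, epsilon=cfg.epsilon)
    export_network(net, out / "network.graphml", "graphml")
    export_network(net, out / "network_edges.tsv", "edge-tsv")
    export_network(net, out / "network_nodes.tsv", "node-tsv")
    proj_frames = []
    for region in table.groups:
        proj_frames.append(regional_projection(net, region))
    if proj_frames:
        pd.concat(proj_frames, ignore_index=True).to_csv(
            out / "network_regional.tsv", sep="\t", index=False)
    done()

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
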