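"""Config-driven orchestration of the full analysis chain.

A run reads an alignment plus population map, then executes: haplotype
collapsing and site classification -> diversity summaries -> median-
joining network -> AMOVA (one pass per grouping scheme) and pairwise
Fst -> per-group mismatch/neutrality demography -> expansion dating.
All stochastic stages take the run seed; reports are TSV/JSON plus a
GraphML network, with a JSON run log recording seed, versions and
per-stage timing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, coalsim, demography, diversity, hapnet, structure
from .alignment_io import (
    classify_sites,
    collapse_haplotypes,
    distance_matrix,
    group_mean_k2p,
    read_alignment,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta: str
    popmap: str
    out_dir: str
    seed: int = 0
    schemes: dict[str, dict[str, str]] = field(default_factory=dict)
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    n_simulations: int = 1000
    weight_transition: int = 1
    weight_transversion: int = 5
    epsilon: int = 0
    calibration: dict | None = None  # clade_divergence_K2P, divergence_time, L, generation_time
    demography_by: str = "group"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _fail_fast(cfg: RunConfig, aln, pm) -> None:
    """Resolve every reference before any computation starts."""
    pm.validate_against(aln)
    for name, mapping in cfg.schemes.items():
        missing = [p for p in pm.populations() if p not in mapping]
        if missing:
            raise ValueError(
                f"scheme {name!r} missing populations: {missing}"
            )
        unknown = [p for p in mapping if p not in pm.populations()]
        if unknown:
            raise ValueError(f"scheme {name!r} references unknown populations: {unknown}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the machine-readable results dict that is
    also written to ``results.json``. Any stage error aborts with the stage
    name; outputs of completed stages are preserved on disk."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": cfg.seed, "version": __version__, "stages": {}}
    results: dict = {}
    t_start = time.time()

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.time()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                log["stages"][name] = round(time.time() - self.t0, 3)
                if exc is not None:
                    log["failed_stage"] = name
                    (out / "run_log.json").write_text(json.dumps(log, indent=2))
                    logger.error("stage %s failed: %s", name, exc)
                return False

        return _Timer()

    with stage("read"):
        aln, pm = read_alignment(cfg.fasta, cfg.popmap)
        _fail_fast(cfg, aln, pm)

    with stage("collapse"):
        haps = collapse_haplotypes(aln, pm)
        sites = classify_sites(haps)
        results["haplotypes"] = {"n_samples": aln.n, "n_haplotypes": haps.n_haplotypes}
        results["sites"] = {
            "conserved": sites.conserved_sites,
            "variable": sites.variable_sites,
            "singleton": sites.singleton_sites,
            "parsimony_informative": sites.parsimony_informative_sites,
            "transitions": sites.transitions,
            "transversions": sites.transversions,
            "ts_tv_ratio": sites.ts_tv_ratio,
            "tv_ts_ratio": sites.tv_ts_ratio,
        }

    with stage("diversity"):
        rows = diversity.diversity_report(aln, pm, out / "diversity.tsv",
                                          by=cfg.demography_by)
        results["diversity"] = {
            label: {"n": s.n, "n_haplotypes": s.n_haplotypes, "Hd": s.Hd,
                    "pi": s.pi, "S": s.S, "k_bar": s.k_bar}
            for label, s in rows
        }

    with stage("network"):
        ncfg = hapnet.NetworkConfig(
            weight_transversion=cfg.weight_transversion,
            weight_transition=cfg.weight_transition,
            epsilon=cfg.epsilon,
        )
        net = hapnet.median_joining(haps, ncfg)
        hapnet.export_network(net, out / "network.graphml", "graphml")
        hapnet.export_network(net, out / "network.tsv", "tsv")
        results["network"] = {
            "n_nodes": net.number_of_nodes(),
            "n_median_vectors": sum(1 for _, d in net.nodes(data=True) if d["inferred"]),
            "n_edges": net.number_of_edges(),
            "cost": hapnet.network_cost(net),
        }

    with stage("distances"):
        dm_raw = distance_matrix(aln, "raw")
        dm_k2p = distance_matrix(aln, "k2p")
        dm_k2p.to_tsv(out / "k2p_distances.tsv")
        group_pairs = {}
        groups = pm.groups()
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                group_pairs[f"{ga}/{gb}"] = round(
                    group_mean_k2p(dm_k2p, pm, ga, gb), 6
                )
        results["group_mean_k2p"] = group_pairs

    with stage("amova"):
        amova_rows = []
        for name, mapping in cfg.schemes.items():
            scheme = structure.GroupingScheme(name, mapping)
            amova_rows.append(
                structure.amova(dm_raw, pm, scheme, cfg.n_permutations, cfg.seed)
            )
        if not cfg.schemes:
            scheme = structure.GroupingScheme("groups", dict(pm.pop_to_group))
            amova_rows.append(
                structure.amova(dm_raw, pm, scheme, cfg.n_permutations, cfg.seed)
            )
        structure.amova_report(amova_rows, out / "amova.tsv")
        results["amova"] = {
            r.scheme: {"Phi_ST": r.Phi_ST, "Phi_SC": r.Phi_SC, "Phi_CT": r.Phi_CT,
                       "p_ST": r.p_ST, "p_SC": r.p_SC, "p_CT": r.p_CT,
                       "pct": [r.pct_a, r.pct_b, r.pct_c]}
            for r in amova_rows
        }

    with stage("fst"):
        fst = structure.pairwise_fst(dm_raw, pm, cfg.n_permutations, cfg.seed)
        fst.to_tsv(out / "pairwise_fst.tsv")
        off_diag = fst.fst[~np.eye(len(fst.populations), dtype=bool)]
        finite = off_diag[np.isfinite(off_diag)]
        results["fst"] = {
            "min": float(finite.min()) if finite.size else None,
            "max": float(finite.max()) if finite.size else None,
        }

    with stage("demography"):
        cal = demography.RateCalibration(**cfg.calibration) if cfg.calibration else None
        demo = {}
        units = {}
        for sid in aln.ids:
            key = (pm.group_of_sample(sid) if cfg.demography_by == "group"
                   else pm.population(sid))
            units.setdefault(key, []).append(sid)
        table_rows = []
        for label in sorted(units):
            sub_ids = units[label]
            if len(sub_ids) < 4:
                continue
            sub = aln.subset(sub_ids)
            hist = demography.mismatch_histogram(sub)
            np.savetxt(out / f"mismatch_{label}.tsv", hist, header="frequency")
            fit = demography.fit_sudden_expansion(hist, sub.n, cfg.seed, cfg.n_bootstrap)
            fs = demography.fu_fs(sub, cfg.seed, cfg.n_simulations)
            r2 = demography.r2_test(sub, cfg.seed, cfg.n_simulations)
            row = {
                "n": sub.n, "Fs": fs.Fs, "p_Fs": fs.p_Fs, "R2": r2.R2,
                "p_R2": r2.p_R2, "SSD": fit.SSD, "p_SSD": fit.p_SSD,
                "rg": fit.rg, "p_rg": fit.p_rg, "tau": fit.tau,
                "tau_CI": list(fit.tau_CI),
            }
            if cal is not None:
                t, ci = demography.date_expansion(fit.tau, cal, fit.tau_CI)
                row["t_mya"] = demography.years_to_mya(t)
                row["t_CI_mya"] = [demography.years_to_mya(ci[0]),
                                   demography.years_to_mya(ci[1])]
            demo[label] = row
            table_rows.append((label, row))
        results["demography"] = demo
        with open(out / "demography.tsv", "w") as fh:
            cols = ["unit", "n", "Fs", "p_Fs", "R2", "p_R2", "SSD", "p_SSD",
                    "rg", "p_rg", "tau", "tau_lo", "tau_hi", "t_mya",
                    "t_lo_mya", "t_hi_mya"]
            fh.write("\t".join(cols) + "\n")
            for label, row in table_rows:
                vals = [label, row["n"], row["Fs"], row["p_Fs"], row["R2"],
                        row["p_R2"], row["SSD"], row["p_SSD"], row["rg"],
                        row["p_rg"], row["tau"], row["tau_CI"][0], row["tau_CI"][1],
                        row.get("t_mya", "NA"),
                        row.get("t_CI_mya", ["NA", "NA"])[0],
                        row.get("t_CI_mya", ["NA", "NA"])[1]]
                fh.write("\t".join(
                    f"{v:.6g}" if isinstance(v, float) else str(v) for v in vals
                ) + "\n")

    log["total_seconds"] = round(time.time() - t_start, 3)
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    (out / "results.json").write_text(json.dumps(results, indent=2, default=float))
    return results
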