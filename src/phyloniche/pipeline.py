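"""Config-driven orchestration: reproduce the analysis shape end-to-end.

A run is described by a YAML config (paths, parameters, seed, output
directory).  Every report embeds the config hash and the seed, and a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from ._errors import ValidationError
from . import alignment as aln_io
from . import dating, enm, overlap, popgen

log = logging.getLogger("phyloniche")


DEFAULTS = {
    "seed": 0,
    "out_dir": "phyloniche_out",
    "site_policy": "complete_sites",
    "n_perm_amova": 20_000,
    "n_perm_pairwise": 10_000,
    "clock_rate": 0.02,
    "n_boot": 500,
    "enm": {"n_background": 10_000, "reg": 0.1, "tol": 1e-5, "max_iter": 500},
    "overlap_reps": 100,
    "train_fraction": 0.25,
    "thin_degrees": 0.1,
    "prune_r": 0.8,
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULTS))  # deep copy
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    cfg["_hash"] = config_hash(cfg)
    return cfg


def config_hash(cfg: dict) -> str:
    clean = {k: v for k, v in cfg.items() if not k.startswith("_")}
    return hashlib.sha256(
        json.dumps(clean, sort_keys=True).encode()
    ).hexdigest()[:12]


def _provenance(cfg: dict) -> str:
    return f"# config_hash={cfg.get('_hash', '?')}\tseed={cfg.get('seed')}\n"


def _stars(p: float | None) -> str:
    if p is None:
        return "na"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _require(cfg: dict, *keys: str) -> None:
    missing = [k for k in keys if k not in cfg]
    if missing:
        raise ValidationError(f"config missing required key(s): {missing}")
    for k in keys:
        v = cfg[k]
        paths = v.values() if isinstance(v, dict) else [v]
        for p in paths:
            if isinstance(p, str) and not Path(p).exists():
                raise ValidationError(f"config key '{k}': path does not exist: {p}")


def _load_alignment(cfg: dict):
    paths = cfg["alignments"]
    if isinstance(paths, str):
        paths = {"locus": paths}
    alns = [aln_io.read_fasta_alignment(p, name) for name, p in paths.items()]
    combined = alns[0]
    for a in alns[1:]:
        combined = aln_io.concatenate(combined, a)
    pops = aln_io.read_assignment(cfg["populations"], cfg.get("groups"))
    pops.validate_against(combined)
    return combined, pops


def run_popgen(cfg: dict) -> dict:
    """Diversity table, pairwise differentiation table, AMOVA report."""
    _require(cfg, "alignments", "populations")
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    combined, pops = _load_alignment(cfg)
    log.info("popgen: %d samples, %d sites, %d populations",
             combined.n_samples, combined.n_sites, len(pops.populations()))

    table = aln_io.collapse_haplotypes(combined, pops, cfg["site_policy"])
    aln_io.write_haplotype_table(table, out / "haplotypes.tsv")
    aln_io.write_haplotype_assignment(table, out / "haplotype_assignment.tsv")

    # per-group (or per-population) diversity summary
    layer = pops.pop_to_group
    units = (sorted(set(layer.values())) if layer else sorted(pops.populations()))
    with open(out / "diversity.tsv", "w") as fh:
        fh.write(_provenance(cfg))
        fh.write("group\tN\tH\tHd\tpi\tS\ttajima_D\tfu_Fs\n")
        for unit in units:
            if layer:
                samples = [s for s, p in pops.sample_to_pop.items()
                           if layer.get(p) == unit]
            else:
                samples = pops.samples_in_pop(unit)
            if len(samples) < 2:
                log.warning("group %s has <2 samples; skipped", unit)
                continue
            stats = popgen.diversity_stats(combined.subset(samples), cfg["site_policy"])
            d = "na" if stats.tajima_D is None else f"{stats.tajima_D:.3f}"
            fs = "na" if stats.fu_Fs is None else f"{stats.fu_Fs:.3f}"
            fh.write(f"{unit}\t{stats.n}\t{stats.H}\t{stats.Hd:.3f}\t"
                     f"{stats.pi:.5f}\t{stats.S}\t{d}\t{fs}\n")

    dm = popgen.raw_difference_matrix(combined, cfg["site_policy"])
    # pairwise differentiation among groups (groups as populations if defined)
    if layer:
        s2g = {s: layer[p] for s, p in pops.sample_to_pop.items()}
        pair_pops = aln_io.PopulationAssignment(s2g)
    else:
        pair_pops = pops
    pw = popgen.pairwise_phist(dm, pair_pops, cfg["n_perm_pairwise"], cfg["seed"])
    names = sorted({n for pair in pw for n in pair})
    with open(out / "differentiation.tsv", "w") as fh:
        fh.write(_provenance(cfg))
        fh.write("group\t" + "\t".join(names) + "\n")
        for a in names:
            cells = []
            for b in names:
                if a == b:
                    cells.append("")
                    continue
                res = pw.get((a, b)) or pw.get((b, a))
                phi, p, nm = res
                if names.index(a) > names.index(b):  # lower triangle: Phi + stars
                    cells.append("na" if phi is None else f"{phi:.3f}{_stars(p)}")
                else:  # upper triangle: Nm
                    cells.append("na" if nm is None else f"{nm:.2f}")
            fh.write(a + "\t" + "\t".join(cells) + "\n")

    report: dict = {"config_hash": cfg["_hash"], "seed": cfg["seed"]}
    if layer:
        res = popgen.amova(dm, pops, cfg["n_perm_amova"], cfg["seed"])
        report["amova"] = {
            "sigma2_a": res.sigma2_a, "sigma2_b": res.sigma2_b,
            "sigma2_c": res.sigma2_c, "phi_CT": res.phi_CT,
            "phi_SC": res.phi_SC, "phi_ST": res.phi_ST,
            "p_CT": res.p_CT, "p_SC": res.p_SC, "p_ST": res.p_ST,
            "df": res.df, "ssd": res.ssd,
        }
    with open(out / "popgen_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_dating(cfg: dict) -> dict:
    """Per-group-pair net distances, bootstrap CIs and clock dates."""
    _require(cfg, "alignments", "populations")
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    combined, pops = _load_alignment(cfg)
    layer = pops.pop_to_group or {p: p for p in pops.populations()}
    groups = sorted(set(layer.values()))
    rate = cfg["clock_rate"]
    log.info("dating: clock %.4f subs/site/My between lineages "
             "(%.4f per lineage)", rate, rate / 2.0)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            gx, gy = groups[i], groups[j]
            sx = [s for s, p in pops.sample_to_pop.items() if layer[p] == gx]
            sy = [s for s, p in pops.sample_to_pop.items() if layer[p] == gy]
            est = dating.date_divergence(
                combined.subset(sx), combined.subset(sy),
                clock_rate=rate, n_boot=cfg["n_boot"], seed=cfg["seed"],
                group_x=gx, group_y=gy,
            )
            rows.append(est)
    with open(out / "divergence.tsv", "w") as fh:
        fh.write(_provenance(cfg))
        fh.write("group_x\tgroup_y\tPiX\tPiY\tPiXY\tD\tci_low\tci_high\t"
                 "t_Ma\tt_low\tt_high\n")
        for e in rows:
            t = "na" if e.t is None else f"{e.t:.3f}"
            fh.write(f"{e.group_x}\t{e.group_y}\t{e.pi_x:.5f}\t{e.pi_y:.5f}\t"
                     f"{e.pi_xy:.5f}\t{e.D:.5f}\t{e.ci_low:.5f}\t{e.ci_high:.5f}\t"
                     f"{t}\t{e.t_low:.3f}\t{e.t_high:.3f}\n")
    return {"config_hash": cfg["_hash"], "pairs": len(rows)}


def run_niche(cfg: dict) -> dict:
    """Per-lineage niche models, AUC, LPT maps and the overlap test table."""
    _require(cfg, "rasters", "occurrences")
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    env = enm.read_env_stack(cfg["rasters"])
    env, dropped = enm.prune_correlated_layers(env, cfg["prune_r"],
                                               cfg.get("layer_priority"))
    for keep, lose, r in dropped:
        log.warning("pruned layer %s (r=%.3f with %s)", lose, r, keep)
    fit_settings = dict(cfg["enm"])
    occ_sets = {}
    for lineage, path in cfg["occurrences"].items():
        occ = enm.read_occurrences(path, lineage)
        occ = enm.thin_occurrences(occ, cfg["thin_degrees"])
        occ_sets[lineage] = occ

    results: dict = {"config_hash": cfg["_hash"], "seed": cfg["seed"],
                     "pruned": [list(d) for d in dropped], "lineages": {}}
    import numpy as np

    rng = np.random.default_rng(cfg["seed"])
    for lineage, occ in occ_sets.items():
        train, test = enm.train_test_split(occ, cfg["train_fraction"],
                                           int(rng.integers(2**31)))
        model = enm.MaxentModel(**fit_settings, seed=int(rng.integers(2**31)))
        model.fit(train, env)
        auc = enm.evaluate_auc(model, env, test)
        surface = model.predict(env, form="logistic")
        thr, suitable = enm.lpt_threshold(surface, env, train)
        enm.write_ascii_grid(out / f"suitability_{lineage}.asc", surface.values,
                             env.xllcorner, env.yllcorner, env.cellsize)
        enm.write_ascii_grid(out / f"suitable_lpt_{lineage}.asc",
                             suitable.astype(float), env.xllcorner,
                             env.yllcorner, env.cellsize)
        (out / f"model_{lineage}.json").write_text(model.to_json())
        results["lineages"][lineage] = {"n_occ": len(occ), "auc": auc,
                                        "lpt_threshold": thr}
        log.info("lineage %s: AUC=%.3f LPT=%.4f", lineage, auc, thr)

    pairs = cfg.get("overlap_pairs")
    if pairs is None:
        names = list(occ_sets)
        pairs = [[names[i], names[j]] for i in range(len(names))
                 for j in range(i + 1, len(names))]
    with open(out / "overlap.tsv", "w") as fh:
        fh.write(_provenance(cfg))
        fh.write("pair\tD\tI\tidentity_p_D\tidentity_p_I\t"
                 "bg_AvB_p_D\tbg_AvB_p_I\tbg_BvA_p_D\tbg_BvA_p_I\tsignif\n")
        for a, b in pairs:
            ident = overlap.identity_test(occ_sets[a], occ_sets[b], env,
                                          fit_settings, cfg["overlap_reps"],
                                          int(rng.integers(2**31)))
            ab, ba = overlap.background_test_pair(occ_sets[a], occ_sets[b], env,
                                                  fit_settings,
                                                  cfg["overlap_reps"],
                                                  int(rng.integers(2**31)))
            fh.write(f"{a} vs {b}\t{ident.observed_D:.3f}\t{ident.observed_I:.3f}\t"
                     f"{ident.p_D:.3f}\t{ident.p_I:.3f}\t"
                     f"{ab.p_D:.3f}\t{ab.p_I:.3f}\t{ba.p_D:.3f}\t{ba.p_I:.3f}\t"
                     f"{_stars(ident.p_D)}\n")
    with open(out / "niche_report.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    return results
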