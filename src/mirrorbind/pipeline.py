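"""End-to-end design pipeline on generated toy complexes.

Stages: prepare -> sample -> cluster -> scan -> curate -> ti -> combine ->
report.  Every stage writes its outputs plus a manifest (config hash, seed)
into the run directory; a rerun with the same config and seed reuses cached
stages and recomputes only what is missing.  All numeric outputs are pure
functions of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alchemy, conformers, curation, designer, ffmodel, mutscan, structio, toyfactory
from .alchemy import AlchemicalSystem, WindowProtocol, derive_seed
from .ffmodel import AlchemicalTopology, TypedSystem
from .sampler import SamplerConfig, sample
from .structio import Structure

__all__ = ["DEFAULT_CONFIG", "PipelineError", "load_config", "run_pipeline",
           "make_mutation_systems", "STAGE_ORDER"]

STAGE_ORDER = ["prepare", "sample", "cluster", "scan", "curate", "ti", "combine", "report"]


class PipelineError(RuntimeError):
    pass


# Defaults mirror the published protocol parameters (300 K, 12 A nonbonded
# cutoff in the packaged force field, 2.0 A cluster radius, 5 A interface
# cutoff, 9 lambda windows, 4.0 A stability gate, 2.0 kcal/mol combination
# threshold, 100 scan repeats); toy-scale budgets are set per run config.
DEFAULT_CONFIG: dict = {
    "toy": {
        "n_host_beads": 5,
        "n_ligand_res": 3,
        "gap": 5.5,
        "planted": [{"kind": "salt_bridge", "position": 2, "code": "DPP"}],
        "preferred_mutation": None,
        "scaffold": "ALA",
    },
    "sample": {"n_steps": 3000, "stride": 30, "move_scale": 0.12, "temperature": 300.0},
    "cluster": {"radius": 2.0},
    "scan": {
        "alphabet": ["GLY", "ALA", "SER", "ASP", "LYS", "PHE", "DPP", "26P", "ABA"],
        "n_repeats": 100,
        "interface_cutoff": 5.0,
        "max_backbones": 3,
    },
    "curate": {"contact_cutoff": 5.0},
    "ti": {
        "max_candidates": 2,
        "windows": 9,
        "equil_steps": 300,
        "prod_steps": 1500,
        "stride": 3,
        "move_scale": 0.3,
        "gate_threshold": 4.0,
    },
    "combine": {"threshold": 2.0, "orders": [2]},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for section, values in user.items():
        if section in cfg and isinstance(values, dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


class _Run:
    """Stage bookkeeping: manifests, caching, logging."""

    def __init__(self, cfg: dict, out: Path, seed: int, resume: bool = True):
        self.cfg = cfg
        self.out = Path(out)
        self.seed = seed
        self.resume = resume
        self.out.mkdir(parents=True, exist_ok=True)
        self.log_path = self.out / "run.log"

    def log(self, msg: str) -> None:
        with open(self.log_path, "a") as fh:
            fh.write(msg + "\n")

    def manifest(self, stage: str) -> Path:
        return self.out / f"{stage}.manifest.json"

    def fingerprint(self, stage: str) -> str:
        idx = STAGE_ORDER.index(stage)
        return _hash({
            "seed": self.seed,
            "stages": {s: self.cfg.get(s.replace("report", "combine"), {})
                       for s in STAGE_ORDER[: idx + 1]},
            "toy": self.cfg["toy"],
        })

    def cached(self, stage: str, outputs: list[str]) -> bool:
        mpath = self.manifest(stage)
        if not (self.resume and mpath.exists()):
            return False
        try:
            m = json.loads(mpath.read_text())
        except json.JSONDecodeError:
            return False
        return m.get("fingerprint") == self.fingerprint(stage) and all(
            (self.out / o).exists() for o in outputs
        )

    def done(self, stage: str, outputs: list[str]) -> None:
        self.manifest(stage).write_text(json.dumps({
            "stage": stage,
            "fingerprint": self.fingerprint(stage),
            "seed": self.seed,
            "outputs": outputs,
        }, indent=1))
        self.log(f"stage {stage} complete (seed={self.seed})")


# ---------------------------------------------------------------------------
# alchemical mutation topology for guest residues
# ---------------------------------------------------------------------------

def _best_mutation_chis(s: Structure, position, code, ff, lib):
    best, best_chis = np.inf, None
    for chis in mutscan.expand_rotamers(lib, code):
        mut = mutscan.mutate_residue(s, position, code, lib, chis=chis)
        sys_ = mutscan.structure_system(mut, ff, lib)
        e = ffmodel.interface_score(sys_)
        if e < best:
            best, best_chis = e, chis
    return best_chis


def make_mutation_systems(
    s: Structure,
    mutations: list[tuple[tuple[str, int], str]],
    ff,
    lib,
    guest_chain: str = "B",
) -> tuple[AlchemicalSystem, AlchemicalSystem]:
    """Dual-topology systems for one or more side-chain mutations, in the
    complex environment and for the free (host-less) guest.

    Native side-chain atoms at each mutated position vanish; mutant
    side-chain atoms (built at their best rotamer) appear.  Only mutating
    side-chain atoms move during TI sampling.
    """
    mut_struct = s
    for position, code in mutations:
        chis = _best_mutation_chis(mut_struct, position, code, ff, lib)
        mut_struct = mutscan.mutate_residue(mut_struct, position, code, lib, chis=chis)

    out = []
    for environment in ("complex", "free"):
        if environment == "complex":
            base = s
            base_mut = mut_struct
        else:
            keep = [r for r in s.residues(0) if r.chain_id == guest_chain]
            base = Structure(models=[[r for r in keep]])
            keep_m = [r for r in mut_struct.residues(0) if r.chain_id == guest_chain]
            base_mut = Structure(models=[[r for r in keep_m]])
        sysA = mutscan.structure_system(base, ff, lib)
        index = {lab: i for i, lab in enumerate(sysA.labels)}
        vanishing: set[int] = set()
        bb = set(mutscan.BACKBONE)
        for position, code in mutations:
            chain, resseq = position
            native = next(r for r in base.residues(0)
                          if (r.chain_id, r.resseq) == (chain, resseq))
            for a in native.atoms:
                if a.name not in bb:
                    vanishing.add(index[f"{chain}:{resseq}:{a.name}"])

        # append mutant side-chain atoms
        coords = list(sysA.coords)
        keys = list(sysA.type_keys)
        eps = list(sysA.eps)
        sig = list(sysA.sig)
        charge = list(sysA.charge)
        chains = list(sysA.chain_ids)
        labels = list(sysA.labels)
        bonds = list(sysA.bonds)
        appearing: set[int] = set()
        for position, code in mutations:
            chain, resseq = position
            mut_res = next(r for r in base_mut.residues(0)
                           if (r.chain_id, r.resseq) == (chain, resseq))
            tmpl = lib.template(code)
            local = {}
            for ta in tmpl.atoms:
                atom = mut_res.atom(ta.name)
                at = ff.type_of(ta.type_key)
                idx = len(coords)
                local[ta.name] = idx
                appearing.add(idx)
                coords.append(atom.coords)
                keys.append(ta.type_key)
                eps.append(at.epsilon)
                sig.append(at.sigma)
                charge.append(at.charge)
                chains.append(chain)
                labels.append(f"{chain}:{resseq}:{ta.name}*")
                if ta.bond_ref in bb:
                    j = index[f"{chain}:{resseq}:{ta.bond_ref}"]
                else:
                    j = local[ta.bond_ref]
                bonds.append((idx, j, 300.0, ta.bond_len))

        union = TypedSystem(
            coords=np.array(coords), type_keys=keys,
            eps=np.array(eps), sig=np.array(sig), charge=np.array(charge),
            chain_ids=chains, ff=ff, bonds=bonds, labels=labels,
        )
        topo = AlchemicalTopology(system=union, vanishing=frozenset(vanishing),
                                  appearing=frozenset(appearing))
        movable = np.array(sorted(vanishing | appearing), dtype=int)
        out.append(AlchemicalSystem(topo=topo, coords=union.coords.copy(),
                                    movable=movable))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _frames_to_structure(s: Structure, frames, sys_labels) -> Structure:
    """Multi-model structure from trajectory frames over the system's atoms."""
    out = s.copy()
    out.models = []
    template = s.models[0]
    lab_index = {lab: i for i, lab in enumerate(sys_labels)}
    for frame in frames:
        model = [r for r in Structure(models=[template]).copy().models[0]]
        for r in model:
            for a in r.atoms:
                a.coords = frame[lab_index[f"{r.chain_id}:{r.resseq}:{a.name}"]].copy()
        out.models.append(model)
    return out


def run_pipeline(config, out_dir, seed: int = 0, resume: bool = True,
                 stop_after: str = "report") -> dict:
    """Run the toy design pipeline; returns the report bundle as a dict."""
    cfg = load_config(config)
    run = _Run(cfg, Path(out_dir), seed, resume=resume)
    ff = mutscan.default_forcefield()
    lib = mutscan.default_library()
    if stop_after not in STAGE_ORDER:
        raise PipelineError(f"unknown stage {stop_after!r}")
    last = STAGE_ORDER.index(stop_after)

    # ---- prepare ---------------------------------------------------------
    tcfg = cfg["toy"]
    plants = [
        {"kind": p["kind"], "position": p["position"], "code": p.get("code")}
        for p in tcfg.get("planted", [])
    ]
    spec = toyfactory.ToySystemSpec(
        n_host_beads=int(tcfg["n_host_beads"]),
        n_ligand_res=int(tcfg["n_ligand_res"]),
        planted_interactions=plants,
        preferred_mutation=tuple(tcfg["preferred_mutation"]) if tcfg.get("preferred_mutation") else None,
        seed=derive_seed(seed, "toy"),
        gap=float(tcfg.get("gap", 5.5)),
        scaffold_code=tcfg.get("scaffold", "ALA"),
    )
    complex_pdb = run.out / "complex.pdb"
    if not run.cached("prepare", ["complex.pdb"]):
        s, _ = toyfactory.make_toy_complex(spec, ff=ff, lib=lib)
        structio.write_structure(s, complex_pdb)
        run.done("prepare", ["complex.pdb"])
    s = structio.read_structure(complex_pdb)
    # restore guest chirality labels (GLY-backbone beads have no CB)
    if last == 0:
        return {"stage": "prepare", "complex": str(complex_pdb)}

    # ---- sample ----------------------------------------------------------
    scfg = cfg["sample"]
    traj_pdb = run.out / "trajectory.pdb"
    energies_tsv = run.out / "energies.tsv"
    sys_full = mutscan.structure_system(s, ff, lib)
    guest_atoms = np.array([i for i, c in enumerate(sys_full.chain_ids) if c == "B"])
    if not run.cached("sample", ["trajectory.pdb", "energies.tsv"]):
        mc_cfg = SamplerConfig(
            temperature=float(scfg["temperature"]),
            n_steps=int(scfg["n_steps"]),
            snapshot_stride=int(scfg["stride"]),
            seed=derive_seed(seed, "sample"),
            move_scale=float(scfg["move_scale"]),
            movable=guest_atoms,
        )
        traj = sample(sys_full.coords, ffmodel.make_energy_fn(sys_full), mc_cfg)
        multi = _frames_to_structure(s, traj.frames, sys_full.labels)
        structio.write_structure(multi, traj_pdb)
        pd.DataFrame({
            "frame": range(len(traj.energies)),
            "energy_kcal_mol": traj.energies,
        }).to_csv(energies_tsv, sep="\t", index=False)
        run.done("sample", ["trajectory.pdb", "energies.tsv"])
    traj_struct = structio.read_structure(traj_pdb)
    if last == 1:
        return {"stage": "sample", "n_frames": traj_struct.n_models}

    # ---- cluster ---------------------------------------------------------
    ccfg = cfg["cluster"]
    clusters_tsv = run.out / "clusters.tsv"
    ensemble_pdb = run.out / "ensemble.pdb"
    frames = []
    backbone_mask = []
    for model in range(traj_struct.n_models):
        coords = []
        for r in traj_struct.residues(model):
            for a in r.atoms:
                if model == 0:
                    backbone_mask.append(
                        r.chain_id == "B" and a.name in conformers.BACKBONE_ATOMS
                    )
                coords.append(a.coords)
        frames.append(np.array(coords))
    mask = np.array(backbone_mask)
    if not run.cached("cluster", ["clusters.tsv", "ensemble.pdb"]):
        cs = conformers.cluster(frames, radius=float(ccfg["radius"]), mask=mask)
        pd.DataFrame(conformers.cluster_table(cs)).to_csv(clusters_tsv, sep="\t", index=False)
        reps = Structure(models=[traj_struct.models[i] for i in cs.representatives])
        structio.write_structure(reps, ensemble_pdb)
        run.done("cluster", ["clusters.tsv", "ensemble.pdb"])
    ensemble_struct = structio.read_structure(ensemble_pdb)
    if last == 2:
        return {"stage": "cluster", "n_clusters": ensemble_struct.n_models}

    # ---- scan ------------------------------------------------------------
    ncfg = cfg["scan"]
    scan_tsv = run.out / "scan.tsv"
    logo_tsv = run.out / "logo.tsv"
    ensemble = [
        Structure(models=[ensemble_struct.models[i]])
        for i in range(min(ensemble_struct.n_models, int(ncfg["max_backbones"])))
    ]
    interface = structio.find_interface(
        [s] + ensemble, "B", {"A"}, cutoff=float(ncfg["interface_cutoff"])
    )
    if len(interface) == 0:
        raise PipelineError("no interface residues found")
    if not run.cached("scan", ["scan.tsv", "logo.tsv"]):
        result = mutscan.scan(
            [s] + ensemble, interface, list(ncfg["alphabet"]), ff, lib,
            n_repeats=int(ncfg["n_repeats"]), seed=derive_seed(seed, "scan"),
        )
        rows = [
            {"position": pos, "code": code, "mean": e.mean, "sd": e.sd,
             "best": e.best, "n": e.n}
            for (pos, code), e in sorted(result.entries.items())
        ]
        pd.DataFrame(rows).to_csv(scan_tsv, sep="\t", index=False)
        logo = mutscan.make_logo(result)
        lrows = [
            {"position": pos, "code": code, "height": h}
            for pos, col in sorted(logo.columns.items())
            for code, h in sorted(col.items())
        ]
        pd.DataFrame(lrows, columns=["position", "code", "height"]).to_csv(
            logo_tsv, sep="\t", index=False)
        run.done("scan", ["scan.tsv", "logo.tsv"])
    scan_df = pd.read_csv(scan_tsv, sep="\t", dtype={"code": str})
    if last == 3:
        return {"stage": "scan", "n_entries": len(scan_df)}

    # ---- curate ----------------------------------------------------------
    ucfg = cfg["curate"]
    curation_tsv = run.out / "curation.tsv"
    natives = {r.resseq: r.name3 for r in s.residues(0) if r.chain_id == "B"}
    negative = scan_df[scan_df["best"] < 0]
    cands = []
    for _, row in negative.iterrows():
        code = str(row["code"])
        if code == natives.get(int(row["position"])):
            continue
        mut = mutscan.mutate_residue(s, ("B", int(row["position"])), code, lib)
        cands.append(curation.Candidate(
            position=("B", int(row["position"])), code=code,
            delta_score=float(row["best"]), structure=mut,
        ))
    ccfg_obj = curation.CurationConfig(contact_cutoff=float(ucfg["contact_cutoff"]))
    report = curation.curate(cands, lib, {"A"}, ccfg_obj)
    if not run.cached("curate", ["curation.tsv"]):
        rows = [
            {"position": c.position[1], "code": c.code, "delta_score": c.delta_score,
             "verdict": "kept", "reason": ""}
            for c in report.kept
        ] + [
            {"position": c.position[1], "code": c.code, "delta_score": c.delta_score,
             "verdict": "removed", "reason": reason}
            for c, reason in report.removed
        ]
        pd.DataFrame(rows, columns=["position", "code", "delta_score", "verdict",
                                    "reason"]).to_csv(curation_tsv, sep="\t", index=False)
        run.done("curate", ["curation.tsv"])
    if last == 4:
        return {"stage": "curate", "kept": len(report.kept),
                "removed": len(report.removed)}

    # ---- ti --------------------------------------------------------------
    tcfg_ti = cfg["ti"]
    ddg_tsv = run.out / "ddg.tsv"
    kept_sorted = sorted(report.kept, key=lambda c: c.delta_score)
    chosen = kept_sorted[: int(tcfg_ti["max_candidates"])]
    schedules = alchemy.default_schedules(n=int(tcfg_ti["windows"]))
    protocol = WindowProtocol(
        minimize_iters=30,
        equil_steps=int(tcfg_ti["equil_steps"]),
        prod_steps=int(tcfg_ti["prod_steps"]),
        stride=int(tcfg_ti["stride"]),
        move_scale=float(tcfg_ti["move_scale"]),
    )
    gate = alchemy.StabilityGate(rmsd_threshold=float(tcfg_ti["gate_threshold"]))
    if not run.cached("ti", ["ddg.tsv"]):
        rows = []
        for cand in chosen:
            label = f"{natives[cand.position[1]]}{cand.position[1]}{cand.code}"
            cx, fr = make_mutation_systems(s, [(cand.position, cand.code)], ff, lib)
            verdict = _apo_gate(fr, gate, protocol, derive_seed(seed, "gate", label))
            res = alchemy.ddG_binding(
                label, cx, fr, schedules=schedules, protocol=protocol,
                master_seed=derive_seed(seed, "ti"), gate_verdict=verdict,
            )
            rows.append({
                "position": cand.position[1], "from": natives[cand.position[1]],
                "to": cand.code, "ddG": res.ddG_bind, "error": res.ddG_err,
                "gate_verdict": "rejected" if res.rejected else "pass",
            })
        pd.DataFrame(rows, columns=["position", "from", "to", "ddG", "error",
                                    "gate_verdict"]).to_csv(ddg_tsv, sep="\t", index=False)
        run.done("ti", ["ddg.tsv"])
    ddg_df = pd.read_csv(ddg_tsv, sep="\t", dtype={"to": str, "from": str})
    if last == 5:
        return {"stage": "ti", "n_mutations": len(ddg_df)}

    # ---- combine ---------------------------------------------------------
    mcfg = cfg["combine"]
    combos_tsv = run.out / "combos.tsv"
    singles = [
        designer.MutationRecord(position=int(r["position"]), from_code=str(r["from"]),
                                to_code=str(r["to"]), ddG=float(r["ddG"]))
        for _, r in ddg_df.iterrows() if r["gate_verdict"] == "pass"
    ]
    selected = designer.select_for_combination(singles, threshold=float(mcfg["threshold"]))
    combo_rows = []
    if not run.cached("combine", ["combos.tsv"]):
        for order in mcfg["orders"]:
            if len(selected) < order:
                continue
            for shell in designer.enumerate_combinations(selected, order):
                muts = [(("B", m.position), m.to_code) for m in shell.members]
                cx, fr = make_mutation_systems(s, muts, ff, lib)
                res = alchemy.ddG_binding(
                    shell.label, cx, fr, schedules=schedules, protocol=protocol,
                    master_seed=derive_seed(seed, "combine"),
                )
                combo_rows.append({
                    "combo": shell.label, "order": order,
                    "ddG": res.ddG_bind, "error": res.ddG_err,
                    "sum_of_singles": sum(m.ddG for m in shell.members),
                })
        pd.DataFrame(combo_rows, columns=["combo", "order", "ddG", "error",
                                          "sum_of_singles"]).to_csv(
            combos_tsv, sep="\t", index=False)
        run.done("combine", ["combos.tsv"])
    combos_df = pd.read_csv(combos_tsv, sep="\t")
    if last == 6:
        return {"stage": "combine", "n_combos": len(combos_df)}

    # ---- report ----------------------------------------------------------
    report_json = run.out / "report.json"
    n_scanned = len(scan_df)
    n_negative = len(negative)
    funnel = designer.funnel_report([
        ("scan", n_scanned, n_negative),
        ("curate", n_negative, n_negative - len(report.removed)),
        ("ti", n_negative - len(report.removed), len(chosen)),
        ("confirmed", len(chosen),
         int((ddg_df["ddG"] < 0).sum())),
    ])
    best_row = None
    candidates_best = []
    if len(ddg_df):
        candidates_best.append(ddg_df.loc[ddg_df["ddG"].idxmin()])
    if len(combos_df):
        candidates_best.append(combos_df.loc[combos_df["ddG"].idxmin()])
    if candidates_best:
        best_row = min(candidates_best, key=lambda r: float(r["ddG"]))
    bundle = {
        "funnel": funnel,
        "n_interface_residues": len(interface),
        "best_ddG": float(best_row["ddG"]) if best_row is not None else None,
        "best_label": (str(best_row.get("combo", "")) or
                       f"{best_row['from']}{best_row['position']}{best_row['to']}")
                      if best_row is not None else None,
        "kd_fold_change": alchemy.kd_fold_change(float(best_row["ddG"]))
                          if best_row is not None else None,
        "outputs": sorted(
            p.name for p in run.out.iterdir() if p.suffix in (".tsv", ".pdb")
        ),
    }
    report_json.write_text(json.dumps(bundle, indent=1))
    run.done("report", ["report.json"])
    return bundle


def _apo_gate(free_system: AlchemicalSystem, gate, protocol, seed: int):
    """Short apo simulations of both endpoints feed the stability gate."""
    trajs = []
    for stage, lam in (("decharge", 0.0), ("recharge", 1.0)):
        def u(c, stage=stage, lam=lam):
            return free_system.u_and_dudl(c, stage, lam)[0]
        cfg = SamplerConfig(
            n_steps=max(200, protocol.equil_steps),
            snapshot_stride=10,
            seed=derive_seed(seed, stage),
            move_scale=protocol.move_scale,
            movable=free_system.movable,
        )
        trajs.append(sample(free_system.coords, u, cfg))
    return alchemy.stability_gate(trajs[0], trajs[1], gate)
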