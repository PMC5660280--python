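"""Config-driven analysis pipeline producing a machine-readable interaction report.

The pipeline ties the individual analysis stages (RDF/coordination,
denticity, H-bond occupancies, closest-atom distances, stacking, ligand
RMSD, SASA) into one run over a trajectory, driven by a YAML-style config
mapping. Every referenced selection is resolved and validated *before* any
stage executes, so a bad config fails fast and leaves no partial outputs.
Reports are written with sorted keys and fixed float precision; rerunning
the same config on the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from mdinteract import __version__
from mdinteract.coordination import (
    compute_rdf,
    coordination_series,
    denticity_fractions,
    detect_first_minimum,
    export_profile,
    mean_count_within,
    peak_position,
)
from mdinteract.errors import ConfigurationError, DetectionError, SelectionError
from mdinteract.fluctuations import (
    corrected_heatmap,
    export_matrix,
    ligand_rmsd_series,
    per_residue_rmsd,
)
from mdinteract.interactions import (
    HBondCriteria,
    HBondTriple,
    StackingThresholds,
    classify_stacking,
    distance_series,
    export_contact_table,
    export_series,
    hbond_occupancy,
)
from mdinteract.qmmm_boundary import (
    EmbeddingConfig,
    export_embedding_charges,
    lookup_link_params,
    place_link_atom,
)
from mdinteract.sasa import SasaConfig, sasa_series
from mdinteract.structure_io import Selection, Trajectory, read_multimodel_pdb, select

__all__ = ["load_config", "run_profile", "run_heatmap", "run_link_prep"]


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    cfg["_config_path"] = str(path)
    return cfg


def _config_hash(config: dict) -> str:
    canon = json.dumps(
        {k: v for k, v in config.items() if not k.startswith("_")},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _require(config: dict, key: str) -> object:
    if key not in config:
        raise ConfigurationError(f"config is missing required key {key!r}")
    return config[key]


def _resolve_or_fail(traj: Trajectory, spec: dict, where: str,
                     exactly: int | None = None, nonempty: bool = True) -> np.ndarray:
    try:
        idx = select(traj, spec)
    except SelectionError as exc:
        raise ConfigurationError(f"{where}: {exc}") from exc
    if exactly is not None and len(idx) != exactly:
        raise ConfigurationError(
            f"{where}: selection must match exactly {exactly} atom(s), got {len(idx)}"
        )
    if nonempty and len(idx) == 0:
        raise ConfigurationError(f"{where}: selection matches no atoms")
    return idx


def _hbond_criteria(config: dict) -> HBondCriteria:
    c = config.get("hbond_criteria", {})
    return HBondCriteria(
        max_hydrogen_acceptor_distance=float(c.get("max_distance", 3.0)),
        max_deviation_angle=float(c.get("max_angle", 35.0)),
        angle_vertex=c.get("angle_vertex", "donor"),
    )


def _round(value, ndigits=6):
    if isinstance(value, float):
        return round(value, ndigits)
    if isinstance(value, dict):
        return {k: _round(v, ndigits) for k, v in value.items()}
    if isinstance(value, list):
        return [_round(v, ndigits) for v in value]
    return value


def _write_report(report: dict, out_dir: Path, name: str) -> Path:
    path = out_dir / name
    path.write_text(json.dumps(_round(report), indent=2, sort_keys=True) + "\n")
    return path


def _run_log(out_dir: Path, config: dict, inputs: dict[str, Path]) -> None:
    digests = {
        str(p): hashlib.sha256(p.read_bytes()).hexdigest()[:16] for p in inputs.values()
    }
    log = {
        "tool": "mdinteract",
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.get("seed", 0),
        "input_digests": digests,
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")


def run_profile(config: dict) -> dict:
    """Execute the full interaction profile; returns the report mapping.

    Stages: ion RDF + number integral + first peak/minimum, coordination
    series at the configured (or detected) cutoff, optional carboxylate
    denticity, optional solvent-access count, H-bond contact statistics,
    closest-atom distance series, stacking classification fractions,
    ligand RMSD series, SASA summary.
    """
    traj_path = Path(_require(config, "trajectory"))
    traj = read_multimodel_pdb(traj_path)
    out_dir = Path(config.get("output_dir", "mdinteract_out"))
    criteria = _hbond_criteria(config)

    # --- fail-fast validation of every referenced selection -----------------
    ion_cfg = config.get("ion")
    if ion_cfg:
        _resolve_or_fail(traj, _require(ion_cfg, "center"), "ion.center", exactly=1)
        _resolve_or_fail(traj, _require(ion_cfg, "partners"), "ion.partners")
        if "denticity_pair" in ion_cfg:
            _resolve_or_fail(traj, ion_cfg["denticity_pair"], "ion.denticity_pair", exactly=2)
    solvent_cfg = config.get("solvent")
    if solvent_cfg:
        _resolve_or_fail(traj, _require(solvent_cfg, "partners"), "solvent.partners")
    triples = []
    for i, hb in enumerate(config.get("hbonds", [])):
        where = f"hbonds[{i}]"
        d = _resolve_or_fail(traj, _require(hb, "donor"), f"{where}.donor", exactly=1)
        h = _resolve_or_fail(traj, _require(hb, "hydrogen"), f"{where}.hydrogen", exactly=1)
        a = _resolve_or_fail(traj, _require(hb, "acceptor"), f"{where}.acceptor")
        triples.append((hb, HBondTriple(int(d[0]), int(h[0]), [int(x) for x in a])))
    dist_groups = []
    for i, dd in enumerate(config.get("distances", [])):
        where = f"distances[{i}]"
        ga = _resolve_or_fail(traj, _require(dd, "group_a"), f"{where}.group_a")
        gb = _resolve_or_fail(traj, _require(dd, "group_b"), f"{where}.group_b")
        dist_groups.append((dd, ga, gb))
    stack_cfg = config.get("stacking", {})
    stack_pairs = []
    for i, sp in enumerate(stack_cfg.get("pairs", [])):
        where = f"stacking.pairs[{i}]"
        ra = _resolve_or_fail(traj, _require(sp, "ring_a"), f"{where}.ring_a")
        rb = _resolve_or_fail(traj, _require(sp, "ring_b"), f"{where}.ring_b")
        stack_pairs.append((sp, ra, rb))
    sasa_cfg = config.get("sasa")
    if sasa_cfg:
        _resolve_or_fail(traj, _require(sasa_cfg, "target"), "sasa.target")
        _resolve_or_fail(traj, sasa_cfg.get("context", {}), "sasa.context", nonempty=False)
    rmsd_cfg = config.get("ligand_rmsd")
    if rmsd_cfg:
        _resolve_or_fail(traj, _require(rmsd_cfg, "ligand"), "ligand_rmsd.ligand")
        _resolve_or_fail(traj, _require(rmsd_cfg, "fit"), "ligand_rmsd.fit")

    # --- stages (all results gathered before any file is written) ----------
    report: dict = {"n_frames": traj.n_frames, "n_atoms": traj.n_atoms}
    series_files: list[tuple[str, np.ndarray]] = []
    profile_export = None

    if ion_cfg:
        profile = compute_rdf(
            traj, ion_cfg["center"], ion_cfg["partners"],
            bin_width=float(ion_cfg.get("bin_width", 0.05)),
            r_max=float(ion_cfg.get("r_max", 10.0)),
        )
        try:
            first_min = detect_first_minimum(profile)
        except DetectionError:
            first_min = None
        peak = peak_position(profile)
        cutoff = float(ion_cfg.get("cutoff", first_min if first_min is not None else 0.0))
        if cutoff <= 0:
            raise ConfigurationError(
                "ion.cutoff not given and no RDF first minimum detected"
            )
        cn = coordination_series(traj, ion_cfg["center"], ion_cfg["partners"], cutoff)
        ion_section = {
            "peak_position": peak,
            "first_minimum": first_min,
            "cutoff": cutoff,
            "mean_cn": cn.mean_cn,
        }
        if "denticity_pair" in ion_cfg:
            ion_section["denticity"] = denticity_fractions(
                traj, ion_cfg["center"], ion_cfg["denticity_pair"], cutoff
            )
        if solvent_cfg:
            ion_section["solvent_mean_count"] = mean_count_within(
                traj, ion_cfg["center"], solvent_cfg["partners"],
                float(solvent_cfg.get("radius", 5.0)),
            )
        report["ion"] = ion_section
        profile_export = profile

    contact_rows = []
    for hb, triple in triples:
        stat = hbond_occupancy(traj, triple, criteria)
        contact_rows.append(
            {
                "residue": hb.get("residue", hb.get("name", "?")),
                "group": hb.get("group", "?"),
                "mean_distance": stat.mean_distance,
                "occupancy": stat.occupancy,
            }
        )
    if contact_rows:
        report["contacts"] = contact_rows

    for dd, ga, gb in dist_groups:
        ds = distance_series(traj, ga, gb)
        report.setdefault("distances", {})[dd.get("name", "pair")] = {"mean": ds.mean}
        series_files.append((f"distance_{dd.get('name', 'pair')}.tsv", ds.series))

    if stack_pairs:
        thr = StackingThresholds(
            d_max=float(stack_cfg.get("thresholds", {}).get("d_max", 6.5)),
            theta_parallel=float(stack_cfg.get("thresholds", {}).get("theta_parallel", 30.0)),
            theta_perpendicular=float(stack_cfg.get("thresholds", {}).get("theta_perpendicular", 60.0)),
        )
        stacks = {}
        for sp, ra, rb in stack_pairs:
            classes = [
                classify_stacking(traj.frames[f], ra, rb, thr).value
                for f in range(traj.n_frames)
            ]
            fractions = {
                c: classes.count(c) / traj.n_frames
                for c in ("parallel_displaced", "t_shaped", "unclassified")
            }
            stacks[sp.get("name", "pair")] = fractions
        report["stacking"] = stacks

    if rmsd_cfg:
        series = ligand_rmsd_series(
            traj, rmsd_cfg["ligand"], rmsd_cfg["fit"],
            reference_frame=int(rmsd_cfg.get("reference_frame", 0)),
        )
        report["ligand_rmsd"] = {"mean": float(series.mean()), "max": float(series.max())}
        series_files.append(("ligand_rmsd.tsv", series))

    if sasa_cfg:
        sconf = SasaConfig(
            probe_radius=float(sasa_cfg.get("probe_radius", 1.4)),
            n_sphere_points=int(sasa_cfg.get("n_sphere_points", 960)),
        )
        series, stat = sasa_series(traj, sasa_cfg["target"], sasa_cfg.get("context", {}), sconf)
        report["sasa"] = {
            "mean": stat.mean,
            "sd": stat.sd,
            "ci_half_width": stat.ci_half_width,
            "n": stat.n,
            "level": stat.level,
        }
        series_files.append(("sasa_series.tsv", series))

    # --- outputs ------------------------------------------------------------
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_report(report, out_dir, "report.json")
    if contact_rows:
        export_contact_table(contact_rows, out_dir / "contacts.tsv")
    if profile_export is not None:
        export_profile(profile_export, out_dir / "rdf.tsv", which="density",
                       sidecar={"cutoff": report["ion"]["cutoff"]})
        export_profile(profile_export, out_dir / "rdf_integral.tsv", which="integral")
    for name, series in series_files:
        export_series(series, out_dir / name)
    _run_log(out_dir, config, {"trajectory": traj_path})
    return report


def run_heatmap(config: dict) -> dict:
    """Fluctuation-corrected per-residue RMSD heatmap (loaded vs empty)."""
    traj_path = Path(_require(config, "trajectory"))
    if "empty_trajectory" not in config:
        raise ConfigurationError("heatmap requires an 'empty_trajectory' path")
    empty_path = Path(config["empty_trajectory"])
    loaded = read_multimodel_pdb(traj_path)
    empty = read_multimodel_pdb(empty_path)
    hm_cfg = config.get("heatmap", {})
    fit = hm_cfg.get("fit")
    ref_frame = int(hm_cfg.get("reference_frame", 0))
    residues = hm_cfg.get("residues")

    raw = per_residue_rmsd(loaded, empty, reference_frame=ref_frame,
                           residues=residues, fit=fit)
    self_m = per_residue_rmsd(empty, empty, reference_frame=ref_frame,
                              residues=residues, fit=fit)
    corrected = corrected_heatmap(raw, self_m)

    out_dir = Path(config.get("output_dir", "mdinteract_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    export_matrix(raw.matrix, raw.residue_numbers, out_dir / "heatmap_raw.tsv")
    export_matrix(self_m.matrix, self_m.residue_numbers, out_dir / "heatmap_selffluct.tsv")
    export_matrix(corrected.matrix, corrected.residue_numbers, out_dir / "heatmap_corrected.tsv")
    column_means = {
        str(rn): float(m)
        for rn, m in zip(corrected.residue_numbers, corrected.matrix.mean(axis=0))
    }
    report = {
        "residues": corrected.residue_numbers,
        "skipped_residues": raw.skipped_residues,
        "corrected_column_means": column_means,
    }
    _write_report(report, out_dir, "heatmap_report.json")
    _run_log(out_dir, config, {"trajectory": traj_path, "empty": empty_path})
    return report


def run_link_prep(config: dict) -> dict:
    """Place link atoms for configured cut bonds and export scaled charges."""
    traj_path = Path(_require(config, "trajectory"))
    traj = read_multimodel_pdb(traj_path)
    lp = _require(config, "link_prep")
    basis = lp.get("basis", "TZ")
    frame = traj.frames[int(lp.get("frame", 0))]

    link_atoms = []
    for i, cb in enumerate(lp.get("cut_bonds", [])):
        where = f"link_prep.cut_bonds[{i}]"
        params = lookup_link_params(_require(cb, "residue_type"), basis)
        ia = _resolve_or_fail(traj, {"serial": _require(cb, "c_alpha_serial")},
                              f"{where}.c_alpha", exactly=1)
        ib = _resolve_or_fail(traj, {"serial": _require(cb, "c_beta_serial")},
                              f"{where}.c_beta", exactly=1)
        pos = place_link_atom(frame[ia[0]], frame[ib[0]], params.rho)
        link_atoms.append(
            {
                "residue_type": params.residue_type,
                "basis": basis,
                "rho": params.rho,
                "r0": params.r0,
                "kL": params.kL,
                "position": [float(x) for x in pos],
            }
        )

    out_dir = Path(config.get("output_dir", "mdinteract_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"basis": basis, "link_atoms": link_atoms}

    if "charges_file" in lp:
        raw = np.loadtxt(lp["charges_file"]).ravel()
        if raw.size != traj.n_atoms:
            raise ConfigurationError(
                f"charges file has {raw.size} values for {traj.n_atoms} atoms"
            )
        emb = EmbeddingConfig(scale_factor=float(lp.get("scale_factor", 0.666)))
        qm_idx = select(traj, lp["qm_selection"]) if "qm_selection" in lp else np.empty(0, int)
        pcs = export_embedding_charges(
            frame, mm_atoms=range(traj.n_atoms), raw_charges=raw,
            config=emb, path=out_dir / "point_charges.txt", qm_atoms=qm_idx,
        )
        report["point_charges"] = {
            "n": len(pcs),
            "scale_factor": emb.scale_factor,
            "total_charge": float(pcs.charges.sum()),
        }

    _write_report(report, out_dir, "link_prep_report.json")
    _run_log(out_dir, config, {"trajectory": traj_path})
    return report
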