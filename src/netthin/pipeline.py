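"""End-to-end orchestration: simulate -> preproc -> connect -> composites -> pet -> fit.

A :class:`RunConfig` (constructible from YAML) fixes every stage parameter
and a single global seed; the seed fans out to per-stage seeds by fixed
offsets so the whole run is reproducible.  Each stage writes tidy CSV
outputs to the run directory, and :func:`run_pipeline` finishes with a JSON
manifest recording versions, parameters, and SHA-256 checksums of every
written file — identical config + seed yields identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import netthin
from netthin import io as nio
from netthin.composites import cohort_composites, map_labels_to_vertices, modal_label_atlas, resample_node_masks
from netthin.models import fit_primary_model, fit_stratified_model, prepare_model_table, ModelFit
from netthin.pet import classify_amyloid, flr_dvr, gmm_cutoff, DEFAULT_CUTOFF
from netthin.preproc import preprocess_session
from netthin.synth import (
    CohortConfig,
    SessionConfig,
    generate_cohort,
    generate_roi_uptake_table,
    generate_session,
    generate_templates,
)
from netthin.tbr import (
    bilateral_average,
    cross_network_connectivity,
    network_connectivity,
    network_mask,
    residualize_between_subject,
    tbr_timecourses,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_report"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preproc", "connect", "composites", "pet", "fit")


class PipelineError(RuntimeError):
    """A stage failed or a stage dependency is unsatisfied."""


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one pipeline run (the demo defaults are desk-scale)."""

    outdir: str = "results/demo"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    n_subjects: int = 40
    grid: tuple[int, int, int] = (12, 12, 12)
    n_volumes: int = 120
    tr: float = 3.0
    runs_per_subject: int = 2
    noise_sd: float = 0.3
    nuisance_amplitude: float = 0.5
    band: tuple[float, float] = (0.008, 0.10)
    filter_order: int = 4
    mask_fraction: float = 0.4
    tbr_rcond: float = 0.1
    coupling_scale: float = 5.0
    pib_cutoff: float = DEFAULT_CUTOFF
    fit_cutoff: bool = False
    fc_pib_time: float = -1.0
    write_volumes: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "grid", "band"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def cohort_config(self) -> CohortConfig:
        fe = dataclasses.replace(CohortConfig().fixed_effects, fc_pib_time=self.fc_pib_time)
        return CohortConfig(n_subjects=self.n_subjects, fixed_effects=fe, seed=self.seed + 1)

    def session_config(self, subject_index: int, run_index: int = 0) -> SessionConfig:
        return SessionConfig(
            grid=self.grid,
            n_volumes=self.n_volumes,
            tr=self.tr,
            noise_sd=self.noise_sd,
            nuisance_amplitude=self.nuisance_amplitude,
            seed=self.seed + 1000 + subject_index + 100_000 * run_index,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(state: dict, key: str, stage: str, produced_by: str) -> None:
    if key not in state:
        raise PipelineError(
            f"stage {stage!r} requires outputs of stage {produced_by!r}; "
            f"add {produced_by!r} to the stage selection or point the run at existing outputs"
        )


def _stage_simulate(config: RunConfig, state: dict, outdir: Path) -> None:
    cohort, truth = generate_cohort(config.cohort_config())
    templates = generate_templates(config.session_config(0))
    sessions = []
    for i in range(config.n_subjects):
        coupling = np.ones(templates.n_components)
        coupling[0] = max(0.1, 1.0 + config.coupling_scale * truth.fc[i])
        sessions.append(
            [
                generate_session(templates, config.session_config(i, r), coupling=coupling)
                for r in range(config.runs_per_subject)
            ]
        )
    state["cohort"] = cohort
    state["truth"] = truth
    state["templates"] = templates
    state["sessions"] = sessions
    cohort.to_csv(outdir / "cohort.csv", index=False)
    if config.write_volumes:
        vol_dir = outdir / "volumes"
        vol_dir.mkdir(exist_ok=True)
        nio.save_templates(state["templates"], vol_dir / "templates.nii.gz")
        for i, runs in enumerate(sessions):
            for r, (bold, motion, tissues, _) in enumerate(runs):
                nio.save_bold(bold, vol_dir / f"sub-{i:03d}_run-{r}_bold.nii.gz")
                nio.save_motion(motion, vol_dir / f"sub-{i:03d}_run-{r}_motion.csv")
                nio.save_tissues(tissues, vol_dir / f"sub-{i:03d}_run-{r}_tissues.nii.gz")


def _stage_preproc(config: RunConfig, state: dict, outdir: Path) -> None:
    _require(state, "sessions", "preproc", "simulate")
    cleaned, qc_rows = [], []
    for i, runs in enumerate(state["sessions"]):
        per_run = [
            preprocess_session(bold, motion, tissues, band=config.band, order=config.filter_order)
            for bold, motion, tissues, _ in runs
        ]
        cleaned.append([clean for clean, _ in per_run])
        qc_rows.append(
            {
                "subject": f"S{i:03d}",
                "mean_fd": float(np.mean([qc["mean_fd"] for _, qc in per_run])),
                "n_retained_pcs": float(np.mean([qc["n_retained_pcs"] for _, qc in per_run])),
            }
        )
    state["cleaned"] = cleaned
    state["qc"] = pd.DataFrame(qc_rows)
    state["qc"].to_csv(outdir / "qc.csv", index=False)


def _stage_connect(config: RunConfig, state: dict, outdir: Path) -> None:
    _require(state, "cleaned", "connect", "preproc")
    templates = state["templates"]
    masks = {name: network_mask(templates, name, config.mask_fraction)
             for name in templates.names[:3]}
    rows = []
    for i, runs in enumerate(state["cleaned"]):
        per_run = []
        for clean in runs:
            tc = tbr_timecourses(clean, templates, rcond=config.tbr_rcond)
            dmn = network_connectivity(clean, tc, templates, masks["DMN"])
            fl = network_connectivity(clean, tc, templates, masks["FPCN_L"])
            fr = network_connectivity(clean, tc, templates, masks["FPCN_R"])
            per_run.append(
                {
                    "dmn_raw": dmn,
                    "fpcn_l_raw": fl,
                    "fpcn_r_raw": fr,
                    "fpcn_raw": bilateral_average(fl, fr),
                    "fpcn_in_dmn_raw": cross_network_connectivity(
                        clean, tc, templates, masks["FPCN_L"], masks["DMN"]
                    ),
                    "dmn_in_fpcn_raw": cross_network_connectivity(
                        clean, tc, templates, masks["DMN"], masks["FPCN_L"]
                    ),
                }
            )
        rows.append(
            {"subject": f"S{i:03d}",
             **{k: float(np.mean([r[k] for r in per_run])) for k in per_run[0]}}
        )
    conn = pd.DataFrame(rows).merge(state["qc"], on="subject")
    for col in ("dmn", "fpcn"):
        conn[f"{col}_adj"] = residualize_between_subject(
            conn[f"{col}_raw"].to_numpy(),
            conn["mean_fd"].to_numpy(),
            conn["n_retained_pcs"].to_numpy(),
        )
    state["connectivity"] = conn
    conn.to_csv(outdir / "connectivity.csv", index=False)


def _stage_composites(config: RunConfig, state: dict, outdir: Path) -> None:
    _require(state, "templates", "composites", "simulate")
    _require(state, "cohort", "composites", "simulate")
    rng = np.random.default_rng(config.seed + 7)
    templates = state["templates"]
    # per-"scan" label volumes with a perturbed threshold, then the modal atlas
    node_prob = {j + 1: templates.maps[..., j] / templates.maps[..., j].max()
                 for j in range(min(2, templates.n_components))}
    label_vols = []
    for _ in range(9):
        frac = config.mask_fraction + rng.uniform(-0.05, 0.05)
        vol = np.zeros(templates.grid, dtype=np.int32)
        best = np.zeros(templates.grid)
        for lab, prob in node_prob.items():
            sel = (prob > frac) & (prob > best)
            vol[sel] = lab
            best[sel] = prob[sel]
        label_vols.append(vol)
    atlas = modal_label_atlas(label_vols)

    zoom = 2.0
    from scipy import ndimage
    gm_support = templates.maps.sum(axis=3)
    gray = ndimage.zoom(gm_support / gm_support.max(), zoom, order=1) > 0.1
    node_masks = {lab: (atlas == lab).astype(float) for lab in node_prob}
    labels_hi = resample_node_masks(node_masks, zoom, gray, inclusion_threshold=0.25)

    voxel_hi = templates.voxel_size_mm / zoom
    affine = np.diag([voxel_hi] * 3 + [1.0])
    # synthetic "surface": jittered points around labelled voxels
    labelled = np.argwhere(labels_hi > 0)
    take = rng.choice(len(labelled), size=min(400, len(labelled)), replace=False)
    vertices = labelled[take] * voxel_hi + rng.uniform(-0.5, 0.5, size=(len(take), 3))
    vertex_labels = map_labels_to_vertices(labels_hi, affine, vertices, radius=2.0)

    cohort = state["cohort"]
    rows = []
    for _, r in cohort.iterrows():
        for v in range(len(vertices)):
            rows.append((r["subject"], r["time"], v,
                         r["thickness"] + rng.normal(0.0, 0.02)))
    thick = pd.DataFrame(rows, columns=["subject", "visit_time", "vertex", "thickness"])
    networks = {1: "DMN", 2: "FPCN"}
    comp = cohort_composites(vertex_labels, thick, networks)
    state["composites"] = comp
    comp.to_csv(outdir / "composites.csv", index=False)


def _stage_pet(config: RunConfig, state: dict, outdir: Path) -> None:
    _require(state, "truth", "pet", "simulate")
    roi = generate_roi_uptake_table(state["truth"])
    dvr = flr_dvr(roi)
    cutoff = (
        gmm_cutoff(dvr.to_numpy(), seed=config.seed) if config.fit_cutoff else config.pib_cutoff
    )
    group = classify_amyloid(dvr, cutoff)
    pet = pd.DataFrame(
        {"subject": dvr.index, "flr_dvr": dvr.to_numpy(), "amyloid_group": group.to_numpy()}
    )
    pet.attrs["cutoff"] = cutoff
    state["pet"] = pet
    roi.to_csv(outdir / "roi_uptake.csv", index=False)
    pet.to_csv(outdir / "pet.csv", index=False)


def _stage_fit(config: RunConfig, state: dict, outdir: Path) -> None:
    _require(state, "composites", "fit", "composites")
    _require(state, "connectivity", "fit", "connect")
    _require(state, "pet", "fit", "pet")
    cohort = state["cohort"]
    dmn_ct = state["composites"].query("network == 'DMN'")[
        ["subject", "visit_time", "thickness"]
    ].rename(columns={"visit_time": "time", "thickness": "dmn_ct"})
    fpcn_ct = state["composites"].query("network == 'FPCN'")[
        ["subject", "visit_time", "thickness"]
    ].rename(columns={"visit_time": "time", "thickness": "fpcn_ct_raw"})
    conn = state["connectivity"][["subject", "dmn_adj", "fpcn_adj"]]
    table = (
        cohort.merge(dmn_ct, on=["subject", "time"])
        .merge(fpcn_ct, on=["subject", "time"])
        .merge(conn, on="subject")
        .merge(state["pet"], on="subject")
    )
    table = table.drop(columns=["thickness"]).rename(columns={"dmn_ct": "thickness"})
    prepared = prepare_model_table(table, fc_col="dmn_adj", pib_col="flr_dvr")
    prepared["fpcn_fc"] = prepared["fpcn_adj"] - prepared["fpcn_adj"].mean()
    prepared["fpcn_ct"] = prepared["fpcn_ct_raw"] - prepared["fpcn_ct_raw"].mean()
    prepared.to_csv(outdir / "model_table.csv", index=False)

    fits: dict[str, ModelFit] = {"primary": fit_primary_model(prepared)}
    for grp in ("high", "low"):
        n_grp = prepared.loc[prepared["amyloid_group"] == grp, "subject"].nunique()
        if n_grp >= 5:
            try:
                fits[f"stratified_{grp}"] = fit_stratified_model(prepared, grp)
            except RuntimeError as exc:  # pragma: no cover - size-dependent
                logger.warning("stratified %s fit skipped: %s", grp, exc)
        else:
            logger.info("stratified %s fit skipped: only %d subjects", grp, n_grp)
    state["fits"] = fits
    state["model_table"] = prepared
    report = make_report(fits)
    (outdir / "report.txt").write_text(report)
    summary = {
        name: {
            "primary_term": fit.primary_term,
            "estimate": fit.primary["estimate"],
            "tstat": fit.primary["tstat"],
            "df": fit.primary["df"],
            "pvalue": fit.primary["pvalue"],
            "cohens_d": fit.primary["cohens_d"],
            "n_obs": fit.n_obs,
            "n_subjects": fit.n_subjects,
        }
        for name, fit in fits.items()
    }
    (outdir / "fit_summary.json").write_text(json.dumps(summary, indent=2))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preproc": _stage_preproc,
    "connect": _stage_connect,
    "composites": _stage_composites,
    "pet": _stage_pet,
    "fit": _stage_fit,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order; return the manifest.

    A stage failure aborts the run with the failing stage named; outputs of
    completed stages are retained on disk.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in config.stages if s not in _STAGE_FUNCS]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}")
    state: dict = {}
    t0 = time.time()
    for stage in STAGES:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, state, outdir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    files = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "netthin_version": netthin.__version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages_run": [s for s in STAGES if s in config.stages],
        "elapsed_s": round(time.time() - t0, 3),
        "checksums": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    state["manifest"] = manifest
    return manifest


def make_report(fits: dict[str, ModelFit]) -> str:
    """Human-readable term/t/df/p/d tables for a set of fits (idempotent)."""
    if not fits:
        raise ValueError("need at least one fit to report")
    lines: list[str] = []
    for name, fit in fits.items():
        lines.append(f"== {name} (n_obs={fit.n_obs}, subjects={fit.n_subjects}) ==")
        lines.append(f"{'term':<16}{'estimate':>12}{'t':>9}{'df':>7}{'p':>10}{'d':>8}")
        for term, row in fit.params.iterrows():
            marker = " *" if term == fit.primary_term else ""
            lines.append(
                f"{term:<16}{row['estimate']:>12.4f}{row['tstat']:>9.2f}"
                f"{row['df']:>7.0f}{row['pvalue']:>10.4f}{row['cohens_d']:>8.2f}{marker}"
            )
        lines.append("")
    return "\n".join(lines)
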