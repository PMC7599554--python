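"""Workflow orchestration: chemistry -> shape screen -> QSAR -> report.

The screening protocol's parameters (conformer cap 500, 20 conformers per
rotatable bond, shape cutoff 0.7, 4 persisted alignments per ligand, 0.5 Å
lattice) are the config defaults; a run is fully described by its config
and seed, and the manifest records digests of every stage output so a run
can be reproduced and audited.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .chem import (ConformerSet, Molecule, generate_conformers, load_activity_table,
                   load_analogues, read_smiles_file)
from . import qsar as qsar_mod
from . import shape as shape_mod

__all__ = ["ScreenConfig", "RunManifest", "load_config", "run_screen",
           "report_ranking", "align_library_to_reference"]

log = logging.getLogger("agelascreen")


class IfpThresholds(BaseModel):
    hbond_d_max: float = Field(3.5, gt=0)
    hbond_angle_min: float = Field(120.0, ge=0, le=180)
    halogen_pi_d_max: float = Field(4.0, gt=0)
    shell_d_max: float = Field(4.5, gt=0)


class ScreenConfig(BaseModel):
    """Validated configuration for a full screening run."""

    seed: int = 2020
    shape_cutoff: float = Field(0.7, ge=0.0, le=1.0)
    n_align: int = Field(4, ge=1)
    conformer_cap: int = Field(500, ge=1)
    per_rotatable_bond: int = Field(20, ge=1)
    spacing: float = Field(0.5, gt=0)
    qsar_components: int | None = None   # None = choose at the R^2 plateau
    qsar_max_components: int = Field(7, ge=1)
    ifp: IfpThresholds = IfpThresholds()
    library: str | None = None           # SMILES path; None = packaged analogues
    reference: str = "AA"
    activities: str | None = None        # CSV path; None = packaged table
    out_dir: str = "agelascreen_out"
    search_restarts: int = Field(6, ge=0)
    search_refine_top: int = Field(6, ge=1)

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v):
        if not (0 <= v < 2 ** 31):
            raise ValueError("seed must fit a 31-bit unsigned range")
        return v


def load_config(path) -> ScreenConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ScreenConfig(**data)


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    version: str
    started: str
    stages: list[dict] = dc_field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, str]):
        self.stages.append({"stage": stage, "time": _now(), "outputs": outputs})

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Rigid map (R, t) minimizing ||P @ R.T + t - Q|| (same atom order)."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cq - R @ cp


def align_library_to_reference(confs: dict[str, ConformerSet], reference: str,
                               config: ScreenConfig | None = None
                               ) -> dict[str, np.ndarray]:
    """Best-alignment coordinates of every ligand in one shared frame.

    Uses the top shape alignment per ligand regardless of the screen cutoff
    (the QSAR stage needs every training molecule in one frame). Alignments
    may target different reference conformers, so each result is composed
    with the Kabsch map from its reference conformer onto reference
    conformer 0 — the common training frame.
    """
    config = config or ScreenConfig()
    ref = confs[reference]
    ref0 = ref.heavy_coords(0)
    out = {}
    for name, cs in confs.items():
        hit = shape_mod.best_alignments(
            cs, ref, n_align=1, spacing=config.spacing,
            refine_top=config.search_refine_top, n_restarts=config.search_restarts,
            rng_seed=config.seed)[0]
        a = hit.alignment
        coords = a.apply(cs.heavy_coords(a.query_conformer))
        if a.ref_conformer != 0:
            R, t = _kabsch(ref.heavy_coords(a.ref_conformer), ref0)
            coords = coords @ R.T + t
        out[name] = coords
    return out


def run_screen(config: ScreenConfig) -> RunManifest:
    """Execute the full workflow and write per-stage artifacts.

    Stages: conformer generation -> shape screen vs the reference ->
    QSAR fit on shape-aligned structures vs packaged activities ->
    ranked report. Idempotent for a fixed config + seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_digest=_digest(config.model_dump_json()),
        seed=config.seed, version=__version__, started=_now())

    # stage 0: library
    if config.library:
        mols = {m.name or f"mol{i}": m
                for i, m in enumerate(read_smiles_file(config.library))}
    else:
        mols = load_analogues()
    if not mols:
        raise ValueError("library is empty")
    if config.reference not in mols:
        raise ValueError(f"reference {config.reference!r} not in library")
    log.info("library: %d molecules", len(mols))

    # stage 1: conformers
    t0 = time.time()
    confs = {name: generate_conformers(m, seed=config.seed, cap=config.conformer_cap,
                                       per_rot=config.per_rotatable_bond)
             for name, m in mols.items()}
    log.info("conformers: %s (%.1fs)",
             {n: len(c) for n, c in confs.items()}, time.time() - t0)
    manifest.record("conformers", {n: str(len(c)) for n, c in confs.items()})

    # stage 2: shape screen
    t0 = time.time()
    hits = shape_mod.screen_library(
        list(confs.values()), confs[config.reference], cutoff=config.shape_cutoff,
        n_align=config.n_align, spacing=config.spacing,
        refine_top=config.search_refine_top, n_restarts=config.search_restarts,
        rng_seed=config.seed)
    hits_path = out_dir / "shape_hits.tsv"
    hits.to_csv(hits_path, sep="\t", index=False)
    log.info("shape screen: %d hits (%.1fs)", len(hits), time.time() - t0)
    manifest.record("shape_screen", {"hits": _file_digest(hits_path)})

    # stage 3: QSAR on shape-aligned structures
    t0 = time.time()
    if config.activities:
        import pandas as pd

        table = pd.read_csv(config.activities)
    else:
        table = load_activity_table()
    qsar_summary, predictions = {}, {}
    trainable = [n for n in table["name"] if n in mols]
    if len(trainable) >= 3:
        aligned = align_library_to_reference(
            {n: confs[n] for n in trainable + ([config.reference]
             if config.reference not in trainable else [])},
            config.reference, config)
        frame = qsar_mod.make_frame([aligned[n] for n in trainable],
                                    spacing=config.spacing)
        fields = [qsar_mod.build_field(mols[n], aligned[n], frame)
                  for n in trainable]
        y = table.set_index("name").loc[trainable, "csm_affinity"].to_numpy()
        k = config.qsar_components or qsar_mod.choose_components(
            fields, y, max_components=config.qsar_max_components)
        model = qsar_mod.fit_pls(fields, y, n_components=k, names=trainable)
        predictions = {n: qsar_mod.predict_activity(model, f)
                       for n, f in zip(trainable, fields)}
        qsar_summary = {"n_components": model.n_components,
                        "r2": model.stats.r2, "sd": model.stats.sd,
                        "rmse": model.stats.rmse, "pearson": model.stats.pearson}
        qsar_path = out_dir / "qsar_fit.json"
        qsar_path.write_text(json.dumps(qsar_summary, indent=1))
        manifest.record("qsar", {"fit": _file_digest(qsar_path)})
        log.info("qsar: k=%d R2=%.4f (%.1fs)", k, model.stats.r2, time.time() - t0)

    # stage 4: ranked report
    report = report_ranking(hits, predictions, table)
    report_path = out_dir / "report.tsv"
    report["table"].to_csv(report_path, sep="\t", index=False)
    (out_dir / "report.json").write_text(json.dumps(
        {k: v for k, v in report.items() if k != "table"}, indent=1))
    manifest.record("report", {"report": _file_digest(report_path)})

    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


def report_ranking(hits, predictions: dict[str, float], table):
    """Merge shape, QSAR, and packaged affinity columns into a ranked report.

    Every affinity-like column is ranked (more negative = stronger); rank
    disagreements between columns are flagged, not resolved. Returns a dict
    with the merged DataFrame and per-column rank orders.
    """
    import pandas as pd

    if table["name"].duplicated().any():
        dupes = table.loc[table["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate ligand names in activity table: {dupes}")
    df = table.copy()
    if hits is not None and len(hits):
        best = hits.groupby("query")["sim"].max()
        df["shape_sim"] = df["name"].map(best)
    if predictions:
        df["qsar_pred"] = df["name"].map(predictions)

    rank_orders = {}
    for col in df.columns:
        if col == "name" or not pd.api.types.is_numeric_dtype(df[col]):
            continue
        ascending = col not in ("shape_sim",)  # similarities: larger = better
        order = df.sort_values(col, ascending=ascending)["name"].tolist()
        df[f"rank_{col}"] = df[col].rank(ascending=ascending, method="min").astype("Int64")
        rank_orders[col] = order

    cols = list(rank_orders)
    disagreements = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if rank_orders[cols[i]] != rank_orders[cols[j]]:
                disagreements.append({"columns": [cols[i], cols[j]]})
    return {"table": df, "rank_orders": rank_orders,
            "disagreements": disagreements}
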