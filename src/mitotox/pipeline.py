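"""End-to-end orchestration: published-table reproduction and a fully
synthetic run touching every stage.

Each run writes its configuration, a stage-granular log and a manifest
with the SHA-256 of every numeric output into its output directory, so a
rerun under the same configuration is checkable bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enm, fractal, qstr, synthetic
from .descriptors import compute_descriptors
from .nanotube import build_nanotube_graph, enumerate_table_set

log = logging.getLogger("mitotox")

#: expected statistics blocks of the published models, used as the
#: reproduction gate (values as printed, tolerances per quantity)
TABLE2_EXPECTED = {
    "r_squared": (0.830731, 1e-3),
    "adjusted_r_squared": (0.819811, 1e-3),
    "ss_residual": (15.83245, 1e-2),
    "mse_residual": (0.510724, 1e-3),
    "f_statistic": (76.07035, 0.1),
}
TABLE4_EXPECTED = {
    "r_squared": (0.844404, 1e-3),
    "adjusted_r_squared": (0.828845, 1e-3),
    "ss_residual": (67.46364, 1e-1),
    "mse_residual": (2.248788, 1e-2),
    "f_statistic": (54.26905, 0.1),
}


@dataclass
class PipelineConfig:
    """Per-stage parameters for a full synthetic run."""

    seed: int = 7
    out_dir: str = "runs/latest"
    n_residues: int = 30
    gamma: float = 0.5
    cutoff: float = enm.CONVENTIONAL_CUTOFF
    p_exponent: int = 2
    enm_mode: str = "cutoff"
    n_forces: int = 7
    fractal_method: str = "otsu"
    n_cells: int = 1
    descriptor_names: tuple[str, ...] = ("GNar", "MAXDP", "PW5", "LOC")
    qstr_sigma: float = 0.5
    extra: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _check(report: qstr.RegressionReport, expected: dict) -> list[str]:
    failures = []
    got = report.as_dict()
    for key, (value, tol) in expected.items():
        if abs(got[key] - value) > tol:
            failures.append(f"{key}: got {got[key]:.6f}, expected {value} ± {tol}")
    return failures


def run_table_reproduction(out_dir=None) -> dict:
    """Recompute the published statistics blocks and applicability domains
    from the packaged observed/predicted tables.

    Returns the report bundle; raises RuntimeError if any reproduced
    statistic misses its tolerance.
    """
    bundle: dict = {}
    failures: list[str] = []
    for which, p, model, expected, tag in (
        ("pristine", 2, qstr.pristine_model(), TABLE2_EXPECTED, "table2"),
        ("carboxyl", 3, qstr.cooh_model(), TABLE4_EXPECTED, "table4"),
    ):
        ds = qstr.load_published_dataset(which)
        resid_gap = float(np.max(np.abs(
            ds.table["observed"] - ds.table["predicted"] - ds.table["residual"])))
        report = qstr.report_for_subset(ds, "training", p)
        failures += [f"{tag} {msg}" for msg in _check(report, expected)]
        if resid_gap > 1e-4:
            failures.append(f"{tag}: residual column inconsistent ({resid_gap:.2e})")
        # the authors' descriptor values are not recoverable, so leverage
        # uses the Hamada indices as the geometric design while residuals
        # come from the printed predicted column
        surrogate = qstr.QstrModel(("n", "m"), (0.0, 0.0), 0.0)
        ad = qstr.applicability_domain(surrogate, ds, predicted="predicted")
        bundle[which] = {
            "statistics": report.as_dict(),
            "residual_column_gap": resid_gap,
            "observed_vs_predicted": ds.table[["label", "observed", "predicted", "split"]]
                .to_dict("records"),
            "applicability_domain": {
                "h_star": ad.h_star,
                "n_outside": int(ad.outside.sum()),
            },
        }
        log.info("%s reproduction: R²=%.6f F=%.5f", tag, report.r_squared, report.f_statistic)
    bundle["failures"] = failures
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "table_reproduction.json").write_text(json.dumps(bundle, indent=2))
    if failures:
        raise RuntimeError("table reproduction out of tolerance: " + "; ".join(failures))
    return bundle


def run_full_synthetic(config: PipelineConfig | None = None) -> dict:
    """Synthetic end-to-end run: helix + ligand → unbound/bound PRS maps →
    fractal report; nanotube set → descriptors → QSTR fit.  Deterministic
    under the configured seed; writes a manifest with output checksums."""
    cfg = config or PipelineConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(cfg), indent=2, default=list))
    manifest: dict = {"seed": cfg.seed, "outputs": {}}

    def record(path: Path) -> None:
        manifest["outputs"][path.name] = _sha256(path)

    stage = "structure"
    try:
        scfg = synthetic.SyntheticConfig(seed=cfg.seed, n_residues=cfg.n_residues,
                                         qstr_sigma=cfg.qstr_sigma)
        coords, pdb_text = synthetic.make_helix_structure(scfg, out / "receptor.pdb")
        record(out / "receptor.pdb")
        net = enm.ElasticNetwork(coords, gamma=cfg.gamma, cutoff=cfg.cutoff,
                                 p_exponent=cfg.p_exponent, mode=cfg.enm_mode)
        log.info("structure: %d residues, %d springs", net.n_nodes, enm.contact_count(net))

        stage = "prs"
        unbound = enm.prs_map(net, cfg.n_forces, cfg.seed, "unbound")
        enm.export_map(unbound, out, "lprs_unbound", net, cfg.seed)
        ligand = synthetic.make_ligand_blob(scfg, coords.mean(axis=0), n_atoms=8)
        bnet = enm.bound_condition(net, ligand)
        bound = enm.prs_map(bnet, cfg.n_forces, cfg.seed, "custom")
        bound_sub = bound.submap(enm.receptor_mask(bnet, net.n_nodes))
        enm.export_map(bound_sub, out, "lprs_bound", bnet, cfg.seed)
        for stem in ("lprs_unbound", "lprs_bound"):
            record(out / f"{stem}.csv")
            record(out / f"{stem}.png")
        map_delta = float(np.linalg.norm(bound_sub.response - unbound.response))
        log.info("prs: bound-vs-unbound Frobenius difference %.4g", map_delta)

        stage = "fractal"
        fractal_results = {}
        for name, m in (("unbound", unbound), ("bound", bound_sub)):
            # render the N×N matrix at image scale (nearest-neighbour) so
            # at least 4 box sizes fit under the counting grid
            factor = max(1, -(-128 // m.response.shape[0]))
            image = np.kron(m.response, np.ones((factor, factor)))
            fr = fractal.fractal_report(image, method=cfg.fractal_method)
            fractal_results[name] = fr.as_dict() | {
                "fit_points": {k: list(map(list, v)) for k, v in fr.fit_points.items()}}
        (out / "fractal.json").write_text(json.dumps(fractal_results, indent=2))
        record(out / "fractal.json")

        stage = "descriptors"
        rows = []
        for spec in enumerate_table_set("pristine", n_cells=cfg.n_cells):
            g = build_nanotube_graph(spec)
            d = compute_descriptors(g)
            rows.append({"label": f"{spec.category} {spec.n}.{spec.m}",
                         "n": spec.n, "m": spec.m, "category": spec.category,
                         "functionalization": spec.functionalization,
                         "n_cells": spec.n_cells, **d.as_dict()})
        desc = pd.DataFrame(rows)
        desc.to_csv(out / "descriptors.csv", index=False)
        record(out / "descriptors.csv")

        stage = "qstr"
        dataset = synthetic.make_qstr_dataset(scfg)
        dataset = qstr.split_dataset(dataset, 0.7, seed=cfg.seed)
        names = [n for n in cfg.descriptor_names if n in dataset.table.columns]
        model, report, _ = qstr.fit_ols(dataset, names)
        ad = qstr.applicability_domain(model, dataset)
        qstr_payload = {
            "coefficients": dict(zip(model.descriptor_names, model.coefficients)),
            "intercept": model.intercept,
            "true_coefficients": dataset.true_coefficients,
            "true_intercept": dataset.true_intercept,
            "statistics": report.as_dict(),
            "h_star": ad.h_star,
            "n_outside": int(ad.outside.sum()),
        }
        (out / "qstr.json").write_text(json.dumps(qstr_payload, indent=2))
        record(out / "qstr.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["map_frobenius_difference"] = map_delta
    manifest["fractal"] = fractal_results
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
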