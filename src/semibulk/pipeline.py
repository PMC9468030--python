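"""End-to-end orchestration: simulate -> qc -> signature -> deconvolve ->
co-occurrence -> platform comparison, from one config.

Every stage writes its artifact under the output directory and the run ends
with a manifest recording parameters, seeds and the SHA-256 of every output
file, so a rerun with the same config can be checked for byte-identical
results.  All randomness flows from the single mandatory top-level seed via
spawned child seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compare import (
    cluster_membership_table,
    combine_platforms,
    joint_cluster,
    mixing_fraction,
)
from .cooccurrence import all_pair_tests, dichotomize, rank_pairs
from .deconvolution import deconvolve_matrix
from .io import write_composition_tsv, write_counts_mtx
from .qc import QcThresholds, filter_units, qc_summary
from .signatures import build_signature
from .synthetic import (
    ColocalizationSpec,
    simulate_reference,
    simulate_reference_cells,
    simulate_semibulks,
)

log = logging.getLogger("semibulk.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]

_SIM_DEFAULTS = dict(
    n_genes=300,
    cell_types=4,
    markers_per_type=12,
    mito_fraction=0.05,
    n_units=500,
    depth=5000,
    baseline_alpha=1.0,
    boost=3.0,
    coloc_pairs=[],
    reference_cells_per_type=30,
    reference_cell_depth=2000,
)
_QC_DEFAULTS = dict(min_genes=50, max_mito=0.25)
_SIG_DEFAULTS = dict(markers_per_type=50, min_fold=2.0)
_COOC_DEFAULTS = dict(top_n=15, yates=False, one_directional_filter=False)
_COMPARE_DEFAULTS = dict(
    enabled=True, n_spots=None, k=3, metric="euclidean", linkage="complete"
)


def _merged(defaults: dict, given: dict | None) -> dict:
    out = dict(defaults)
    unknown = set(given or {}) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out.update(given or {})
    return out


@dataclass
class PipelineConfig:
    """Validated per-stage parameters for one pipeline run."""

    seed: int
    outdir: Path
    simulate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    signature: dict = field(default_factory=dict)
    cooccurrence: dict = field(default_factory=dict)
    compare: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError(
                "a seed is mandatory when any stage simulates data"
            )
        self.seed = int(self.seed)
        self.outdir = Path(self.outdir)
        self.simulate = _merged(_SIM_DEFAULTS, self.simulate)
        self.qc = _merged(_QC_DEFAULTS, self.qc)
        self.signature = _merged(_SIG_DEFAULTS, self.signature)
        self.cooccurrence = _merged(_COOC_DEFAULTS, self.cooccurrence)
        self.compare = _merged(_COMPARE_DEFAULTS, self.compare)

    @classmethod
    def from_yaml(cls, path: str | Path, outdir=None, seed=None) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        if seed is not None:
            cfg["seed"] = seed
        if outdir is not None:
            cfg["outdir"] = outdir
        if "seed" not in cfg:
            raise ValueError("config must set a seed")
        return cls(
            seed=cfg["seed"],
            outdir=cfg.get("outdir", "semibulk_run"),
            simulate=cfg.get("simulate", {}),
            qc=cfg.get("qc", {}),
            signature=cfg.get("signature", {}),
            cooccurrence=cfg.get("cooccurrence", {}),
            compare=cfg.get("compare", {}),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _coloc_spec(sim: dict) -> ColocalizationSpec:
    pairs = tuple((a, b, float(s)) for a, b, s in sim["coloc_pairs"])
    return ColocalizationSpec(
        pairs=pairs,
        baseline_alpha=sim["baseline_alpha"],
        boost=sim["boost"],
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages and return the run manifest."""
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    child = np.random.default_rng(cfg.seed).integers(2**31, size=8)
    artifacts: dict[str, Path] = {}
    stages: list[str] = []
    results: dict = {}

    # -- stage 1: simulation --------------------------------------------
    log.info("stage simulate: %s", cfg.simulate)
    sim = cfg.simulate
    try:
        coloc = _coloc_spec(sim)
        ref = simulate_reference(
            n_genes=sim["n_genes"],
            cell_types=sim["cell_types"],
            markers_per_type=sim["markers_per_type"],
            mito_fraction=sim["mito_fraction"],
            seed=int(child[0]),
        )
        sbset = simulate_semibulks(
            ref,
            n_units=sim["n_units"],
            depth=sim["depth"],
            coloc=coloc,
            seed=int(child[1]),
        )
        ref_cells, labels = simulate_reference_cells(
            ref,
            cells_per_type=sim["reference_cells_per_type"],
            depth=sim["reference_cell_depth"],
            seed=int(child[2]),
        )
    except Exception as e:
        raise RuntimeError(f"stage simulate failed: {e}") from e
    artifacts["counts"] = write_counts_mtx(sbset.counts, out / "counts") / "matrix.mtx"
    artifacts["true_compositions"] = write_composition_tsv(
        sbset.true_compositions, out / "true_compositions.tsv"
    )
    stages.append("simulate")

    # -- stage 2: qc -----------------------------------------------------
    try:
        thresholds = QcThresholds(
            min_genes=cfg.qc["min_genes"], max_mito=cfg.qc["max_mito"]
        )
        filtered, report = filter_units(sbset.counts, thresholds)
    except Exception as e:
        raise RuntimeError(f"stage qc failed: {e}") from e
    report_path = out / "qc_discards.tsv"
    report.to_csv(report_path, sep="\t", index=False, float_format="%.10g")
    artifacts["qc_discards"] = report_path
    summary_path = out / "qc_summary.json"
    summary_path.write_text(
        json.dumps(qc_summary(filtered), indent=2, sort_keys=True) + "\n"
    )
    artifacts["qc_summary"] = summary_path
    results["n_units_after_qc"] = filtered.n_units
    stages.append("qc")

    # -- stage 3: signature ----------------------------------------------
    try:
        sig = build_signature(
            ref_cells,
            labels,
            markers_per_type=cfg.signature["markers_per_type"],
            min_fold=cfg.signature["min_fold"],
        )
    except Exception as e:
        raise RuntimeError(f"stage signature failed: {e}") from e
    artifacts["signature"] = sig.to_tsv(out / "signature.tsv")
    stages.append("signature")

    # -- stage 4: deconvolution ------------------------------------------
    try:
        comp = deconvolve_matrix(filtered, sig)
    except Exception as e:
        raise RuntimeError(f"stage deconvolve failed: {e}") from e
    artifacts["composition"] = write_composition_tsv(
        comp, out / "composition.tsv"
    )
    stages.append("deconvolve")

    # -- stage 5: co-occurrence ------------------------------------------
    try:
        presence = dichotomize(comp)
        tests = all_pair_tests(
            presence, continuity_correction=cfg.cooccurrence["yates"]
        )
        ranked = rank_pairs(
            tests,
            top_n=cfg.cooccurrence["top_n"],
            one_directional_filter=cfg.cooccurrence["one_directional_filter"],
        )
    except Exception as e:
        raise RuntimeError(f"stage cooccurrence failed: {e}") from e
    cooc_path = out / "cooccurrence.tsv"
    ranked.to_csv(cooc_path, sep="\t", index=False, float_format="%.10g")
    artifacts["cooccurrence"] = cooc_path
    if len(ranked):
        results["top_pair"] = [ranked.loc[0, "type_a"], ranked.loc[0, "type_b"]]
    stages.append("cooccurrence")

    # -- stage 6: platform comparison ------------------------------------
    if cfg.compare["enabled"]:
        try:
            n_spots = cfg.compare["n_spots"] or sim["n_units"]
            spot_set = simulate_semibulks(
                ref,
                n_units=n_spots,
                depth=sim["depth"],
                coloc=coloc,
                seed=int(child[3]),
            )
            spot_comp = deconvolve_matrix(spot_set.counts, sig)
            pooled = combine_platforms(comp, spot_comp)
            clustering = joint_cluster(
                pooled,
                k=cfg.compare["k"],
                metric=cfg.compare["metric"],
                linkage_method=cfg.compare["linkage"],
            )
            mix = mixing_fraction(clustering, pooled.platform)
            membership = cluster_membership_table(clustering, pooled.platform)
        except Exception as e:
            raise RuntimeError(f"stage compare failed: {e}") from e
        member_path = out / "cluster_membership.tsv"
        membership.to_csv(member_path, sep="\t")
        artifacts["cluster_membership"] = member_path
        results["mixing_fraction"] = mix
        stages.append("compare")

    # -- manifest ---------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "stages": stages,
        "parameters": {
            "simulate": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in cfg.simulate.items()
            },
            "qc": cfg.qc,
            "signature": cfg.signature,
            "cooccurrence": cfg.cooccurrence,
            "compare": cfg.compare,
        },
        "results": results,
        "artifacts": {
            name: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
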