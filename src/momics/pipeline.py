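"""End-to-end pipeline driver.

Stages: preprocess -> select_k -> subtype -> survival (os) -> survival
(dbf) -> label transfer -> differential (protein, metabolite+indicators)
-> enrichment. Every stage writes its outputs and parameters under the
output directory; a manifest records stage status, seed, config hash, and
file checksums so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import differential, integration, io, model_selection, preprocess
from .snmf import fit_subtypes
from .survival import ClinicalTable, compare_subtypes

logger = logging.getLogger(__name__)

STAGES = (
    "preprocess",
    "select_k",
    "subtype",
    "survival_os",
    "survival_dbf",
    "transfer",
    "differential",
    "enrichment",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run."""

    rna_path: str
    clinical_path: str
    out_dir: str
    protein_path: Optional[str] = None
    metabolite_path: Optional[str] = None
    gene_sets_path: Optional[str] = None
    indicator_path: Optional[str] = None
    category_path: Optional[str] = None
    k_range: tuple = (2, 6)
    k: Optional[int] = None  # fixed k skips rank selection
    n_restarts: int = 50
    tau: float = 0.5
    fdr_threshold: float = 0.05
    log_base: float = 2.0
    rna_pseudocount: float = 1.0
    max_iter: int = 2000
    tol: float = 1e-6
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.k_range, list):
            cfg.k_range = tuple(cfg.k_range)
        return cfg

    def validate(self) -> None:
        for attr in ("rna_path", "clinical_path"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        for attr in (
            "protein_path",
            "metabolite_path",
            "gene_sets_path",
            "indicator_path",
            "category_path",
        ):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_comparison(comp, out: Path, prefix: str) -> List[Path]:
    paths = []
    for lab, curve in comp.curves.items():
        df = pd.DataFrame(
            {
                "time": curve.event_times,
                "survival": curve.survival,
                "se": curve.greenwood_se,
                "ci_lower": curve.ci_lower,
                "ci_upper": curve.ci_upper,
            }
        )
        p = out / f"{prefix}_curve_subtype{lab}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    tests = {
        "endpoint": comp.endpoint,
        "group_sizes": {str(k): v for k, v in comp.group_sizes.items()},
        "largest_pair": list(comp.largest_pair),
        "test": {
            "chi_square": comp.test.chi_square,
            "p_value": comp.test.p_value,
            "df": comp.test.df,
            "defined": comp.test.defined,
        },
        "pairwise": {
            f"{a}_vs_{b}": {
                "chi_square": r.chi_square,
                "p_value": r.p_value,
                "defined": r.defined,
            }
            for (a, b), r in comp.pairwise.items()
        },
        "medians": {
            str(lab): comp.curves[lab].median for lab in comp.curves
        },
    }
    p = out / f"{prefix}_tests.json"
    io.write_json(tests, p)
    paths.append(p)
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash excludes the output location so reruns elsewhere are comparable
    hashable = {k: v for k, v in config.as_dict().items() if k != "out_dir"}
    chash = io.config_hash(hashable)
    manifest: dict = {
        "config": config.as_dict(),
        "config_hash": chash,
        "seed": config.seed,
        "stages": {},
        "files": {},
    }

    def finish_stage(name: str, outputs: List[Path], **info) -> None:
        manifest["stages"][name] = {"status": "complete", **info}
        for p in outputs:
            manifest["files"][str(p.relative_to(out))] = io.file_checksum(p)
        io.write_json(manifest, out / "manifest.json")

    def fail(name: str, exc: BaseException):
        manifest["stages"][name] = {"status": "failed", "error": str(exc)}
        io.write_json(manifest, out / "manifest.json")
        raise PipelineError(name, exc) from exc

    state: dict = {}

    # --- preprocess -------------------------------------------------------
    try:
        rna_raw = io.read_matrix(config.rna_path, layer="rna")
        clinical = io.read_clinical(config.clinical_path)
        filtered = preprocess.filter_low_detected(rna_raw)
        norm = preprocess.normalize(
            filtered,
            log_base=config.log_base,
            pseudocount=config.rna_pseudocount,
        )
        norm.provenance["config_hash"] = chash
        norm.provenance["seed"] = config.seed
        path = out / "rna_normalized.tsv"
        io.write_normalized(norm, path)
        state["norm"] = norm
        state["clinical"] = clinical
        finish_stage(
            "preprocess",
            [path],
            n_features_in=rna_raw.n_features,
            n_features_out=norm.n_features,
            n_samples=norm.n_samples,
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("preprocess", exc)

    # --- select_k ---------------------------------------------------------
    try:
        if config.k is not None:
            k_best = int(config.k)
            table = None
        else:
            k_best, table = model_selection.select_k(
                state["norm"],
                k_range=config.k_range,
                n_restarts=config.n_restarts,
                seed=config.seed,
                max_iter=config.max_iter,
                tol=config.tol,
            )
        outputs = []
        if table is not None:
            tpath = out / "quality_metrics.csv"
            table.to_csv(tpath, index=False)
            outputs.append(tpath)
        kpath = out / "k_selected.json"
        io.write_json({"k": k_best, "seed": config.seed,
                       "config_hash": chash}, kpath)
        outputs.append(kpath)
        state["k"] = k_best
        finish_stage("select_k", outputs, k=k_best)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("select_k", exc)

    # --- subtype ----------------------------------------------------------
    try:
        model, cons = fit_subtypes(
            state["norm"],
            state["k"],
            n_restarts=config.n_restarts,
            seed=config.seed,
            tau=config.tau,
            max_iter=config.max_iter,
            tol=config.tol,
        )
        labels = dict(zip(model.sample_ids, (int(x) for x in model.labels)))
        lpath = out / "subtype_labels.csv"
        io.write_labels(labels, lpath)
        gpath = out / "gene_associations.csv"
        model.genes.to_csv(gpath, index=False)
        cpath = out / "consensus.tsv"
        pd.DataFrame(
            cons.C, index=model.sample_ids, columns=model.sample_ids
        ).to_csv(cpath, sep="\t")
        state["model"] = model
        finish_stage("subtype", [lpath, gpath, cpath], k=state["k"])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("subtype", exc)

    # --- survival ---------------------------------------------------------
    for endpoint in ("os", "dbf"):
        stage = f"survival_{endpoint}"
        try:
            comp = compare_subtypes(
                state["model"], state["clinical"], endpoint=endpoint
            )
            outputs = _write_comparison(comp, out, stage)
            finish_stage(
                stage,
                outputs,
                p_value=comp.test.p_value,
                largest_pair=list(comp.largest_pair),
            )
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)

    # --- transfer ---------------------------------------------------------
    try:
        transfers = {}
        outputs = []
        for name, path_attr in (
            ("protein", "protein_path"),
            ("metabolite", "metabolite_path"),
        ):
            p = getattr(config, path_attr)
            if p is None:
                continue
            layer = io.read_matrix(p, layer=name)
            labels, kept, dropped = integration.transfer_labels(
                state["model"], layer.sample_ids
            )
            tpath = out / f"labels_{name}.csv"
            io.write_labels(labels, tpath)
            outputs.append(tpath)
            transfers[name] = {"kept": kept, "dropped": dropped}
            state[f"{name}_matrix"] = layer
            state[f"{name}_labels"] = labels
        finish_stage("transfer", outputs, transfers=transfers)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("transfer", exc)

    # --- differential -----------------------------------------------------
    try:
        pair = None
        outputs = []
        diff_info = {}
        state["diff"] = {}
        for name in ("protein", "metabolite"):
            matrix = state.get(f"{name}_matrix")
            if matrix is None:
                continue
            labels = state[f"{name}_labels"]
            if pair is None:
                sizes: Dict[int, int] = {}
                for v in labels.values():
                    if v > 0:
                        sizes[v] = sizes.get(v, 0) + 1
                pair = tuple(
                    sorted(sizes, key=lambda lab: (-sizes[lab], lab))[:2]
                )
            if name == "metabolite" and config.indicator_path:
                defs = io.read_indicator_definitions(config.indicator_path)
                matrix = differential.compute_indicators(matrix, defs)
            filtered = preprocess.filter_low_detected(matrix)
            norm = preprocess.normalize(filtered, log_base=config.log_base)
            ids = [
                s for s in norm.sample_ids
                if labels.get(s, 0) in pair
            ]
            if len(ids) < 4:
                raise ValueError(
                    f"{name}: too few samples in the two largest subtypes"
                )
            cols = [norm.sample_ids.index(s) for s in ids]
            table = differential.moderated_t_test(
                norm.values[:, cols],
                [labels[s] for s in ids],
                feature_ids=norm.feature_ids,
                fdr_threshold=config.fdr_threshold,
            )
            dpath = out / f"differential_{name}.csv"
            table.to_csv(dpath, index=False)
            outputs.append(dpath)
            state["diff"][name] = table
            diff_info[name] = {
                "n_significant": int(table["significant"].sum()),
                "contrast": list(pair),
            }
        finish_stage("differential", outputs, **diff_info)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("differential", exc)

    # --- enrichment -------------------------------------------------------
    try:
        outputs = []
        info = {}
        if config.gene_sets_path:
            gene_sets = io.read_gmt(config.gene_sets_path)
            model = state["model"]
            rna_selected = set(model.associated_genes())
            rna_universe = len(model.genes)
            rna_scores = {}
            for pw, gs in gene_sets.items():
                members = gs["members"]
                _, score = integration.enrich_hypergeometric(
                    rna_selected,
                    {m for m in members},
                    rna_universe,
                )
                rna_scores[pw] = score
            prot_scores = {}
            prot_table = state["diff"].get("protein")
            if prot_table is not None:
                sel = set(
                    prot_table.loc[prot_table["significant"], "feature"]
                )
                universe = len(prot_table)
                for pw, gs in gene_sets.items():
                    _, score = integration.enrich_hypergeometric(
                        sel, set(gs["members"]), universe
                    )
                    prot_scores[pw] = score
            categories = None
            if config.category_path:
                import yaml

                categories = yaml.safe_load(
                    Path(config.category_path).read_text()
                )
            table = integration.score_table(
                rna_scores, prot_scores, categories
            )
            epath = out / "pathway_scores.csv"
            table.to_csv(epath, index=False)
            outputs.append(epath)
            info["n_pathways"] = len(table)
        finish_stage("enrichment", outputs, **info)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("enrichment", exc)

    return manifest
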