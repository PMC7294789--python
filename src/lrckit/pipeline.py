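"""End-to-end orchestration: survival percentiles -> longevity scores ->
case/control classification -> per-bin SMRs -> frailty contrast, with a
machine-readable run manifest for reproducibility.

Every stage logs one structured line (stage name, rows in/out) so that
exclusion accounting stays auditable, and any stage failure aborts the
run with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .frailty import case_control_contrast
from .life_tables import LifeTableCollection, read_life_tables
from .lrc import LRCConfig, score_pedigrees
from .pedigree import Pedigree, read_pedigree
from .smr import group_smr_table

__all__ = ["RunConfig", "PipelineStageError", "RunResult", "run_pipeline",
           "singleton_vs_family_report"]

logger = logging.getLogger("lrckit.pipeline")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    pedigree_path: str
    life_table_path: str
    out_dir: str
    top_fraction: float = 0.10
    case_cutoff: float = 0.30
    nonclassified_lower: float = 0.20
    alpha: float = 0.05
    contrast_scheme: str = "A"
    contrast_theta: float | None = None
    focal_role: str = "F3"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def lrc_config(self) -> LRCConfig:
        return LRCConfig(
            top_fraction=self.top_fraction,
            case_cutoff=self.case_cutoff,
            nonclassified_lower=self.nonclassified_lower,
        )


@dataclass
class RunResult:
    out_dir: Path
    scores: pd.DataFrame
    classification_counts: pd.DataFrame
    smr_by_bin: pd.DataFrame
    smr_by_label: pd.DataFrame
    contrast: pd.DataFrame | None
    theta: float | None
    singleton_report: pd.DataFrame
    manifest: dict = field(repr=False, default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _persons_frame(pedigrees: list[Pedigree], focal_role: str) -> pd.DataFrame:
    """Survival rows for focal persons: censored unless known dead."""
    rows = []
    for ped in pedigrees:
        for p in ped:
            if p.role_tag != focal_role:
                continue
            rows.append(
                {
                    "person_id": p.person_id,
                    "family_id": p.family_id,
                    "sex": p.sex,
                    "birth_year": p.birth_year,
                    "t": p.age_end if p.age_end is not None else np.nan,
                    "d": 1 if p.vital_status == "dead" else 0,
                    "t0": 0.0,
                    "n_siblings": len(ped.sibling_ids(p.person_id)),
                }
            )
    return pd.DataFrame(rows)


def singleton_vs_family_report(
    scores: pd.DataFrame,
    pedigrees: list[Pedigree],
    tables: LifeTableCollection,
    persons: pd.DataFrame,
    top_fraction: float = 0.10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Decompose the one-long-lived-parent selection by score band.

    Focal persons with at least one deceased parent in the top
    ``top_fraction`` of their cohort are cross-tabulated against the score
    bands (0, 0.2), [0.2, 0.3) and [0.3, 1], and each band's SMR against
    the reference tables is reported.
    """
    ped_by_family = {ped.family_id: ped for ped in pedigrees}
    selected = []
    for row in scores.itertuples(index=False):
        ped = ped_by_family[row.family_id]
        has_ll_parent = False
        for pid in ped.parent_ids(row.person_id):
            parent = ped[pid]
            if (
                parent.vital_status == "dead"
                and parent.age_end is not None
                and parent.birth_year is not None
                and parent.sex is not None
            ):
                pct = tables.get(parent.sex, parent.birth_year).percentile(parent.age_end)
                if pct >= 1.0 - top_fraction:
                    has_ll_parent = True
                    break
        if has_ll_parent and row.score is not None and not pd.isna(row.score):
            selected.append((row.person_id, row.score))
    if not selected:
        return pd.DataFrame(
            columns=["band", "n", "n_missing_age", "observed", "expected",
                     "smr", "ci_low", "ci_high"]
        )
    sel = pd.DataFrame(selected, columns=["person_id", "score"])

    def band(score: float) -> str:
        if score < 0.2:
            return "lrc_(0,0.2)"
        if score < 0.3:
            return "lrc_[0.2,0.3)"
        return "lrc_>=0.3"

    sel["band"] = sel["score"].map(band)
    merged = sel.merge(persons, on="person_id", how="left")
    table = group_smr_table(merged, tables, group_col="band", alpha=alpha)
    return table.rename(columns={"group": "band"})


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full analysis and write its tables, log and manifest.

    Outputs under ``config.out_dir``: ``lrc_scores.tsv``,
    ``classification_counts.tsv``, ``smr_by_bin.tsv``,
    ``smr_by_label.tsv``, ``contrast.tsv`` (when estimable),
    ``singleton_report.tsv``, ``run.log`` and ``manifest.json``.  Given
    identical inputs and config the outputs are bit-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    stage = "setup"
    manifest: dict = {
        "config": asdict(config),
        "inputs": {
            "pedigree": {"path": str(config.pedigree_path),
                         "sha256": _sha256(config.pedigree_path)},
            "life_tables": {"path": str(config.life_table_path),
                            "sha256": _sha256(config.life_table_path)},
        },
        "versions": {
            "lrckit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    try:
        stage = "read_inputs"
        tables = read_life_tables(config.life_table_path)
        pedigrees = read_pedigree(config.pedigree_path)
        n_persons = sum(len(p) for p in pedigrees)
        logger.info("stage=read_inputs families=%d persons=%d tables=%d",
                    len(pedigrees), n_persons, len(tables))
        manifest["stages"]["read_inputs"] = {
            "families": len(pedigrees), "persons": n_persons, "tables": len(tables),
        }

        stage = "lrc_scores"
        lrc_cfg = config.lrc_config()
        scores = score_pedigrees(pedigrees, tables, lrc_cfg, config.focal_role)
        scores.to_csv(out_dir / "lrc_scores.tsv", sep="\t", index=False,
                      float_format="%.10g")
        n_scored = int(scores["score"].notna().sum())
        logger.info("stage=lrc_scores focal=%d scored=%d", len(scores), n_scored)
        manifest["stages"]["lrc_scores"] = {"focal": len(scores), "scored": n_scored}

        stage = "classification"
        counts = (
            scores["label"].value_counts().rename_axis("label")
            .reset_index(name="n").sort_values("label").reset_index(drop=True)
        )
        counts.to_csv(out_dir / "classification_counts.tsv", sep="\t", index=False)
        logger.info("stage=classification labels=%s",
                    dict(zip(counts["label"], counts["n"])))
        manifest["stages"]["classification"] = dict(
            zip(counts["label"], counts["n"].astype(int))
        )

        stage = "group_smr"
        persons = _persons_frame(pedigrees, config.focal_role)
        merged = persons.merge(
            scores[["person_id", "bin", "label"]], on="person_id", how="left"
        )
        binned = merged[merged["bin"].fillna("") != ""].rename(columns={"bin": "group"})
        smr_by_bin = group_smr_table(binned, tables, group_col="group",
                                     alpha=config.alpha).rename(columns={"group": "bin"})
        smr_by_bin.to_csv(out_dir / "smr_by_bin.tsv", sep="\t", index=False,
                          float_format="%.10g")
        labelled = merged[merged["label"].notna()].rename(columns={"label": "group"})
        smr_by_label = group_smr_table(labelled, tables, group_col="group",
                                       alpha=config.alpha).rename(columns={"group": "label"})
        smr_by_label.to_csv(out_dir / "smr_by_label.tsv", sep="\t", index=False,
                            float_format="%.10g")
        logger.info("stage=group_smr bins=%d labels=%d",
                    len(smr_by_bin), len(smr_by_label))
        manifest["stages"]["group_smr"] = {
            "bins": smr_by_bin[["bin", "n", "smr"]].to_dict("records"),
        }

        stage = "contrast"
        contrast_df: pd.DataFrame | None = None
        theta: float | None = None
        records = _contrast_records(pedigrees, merged, config)
        try:
            fit = case_control_contrast(
                records, scheme=config.contrast_scheme,
                theta=config.contrast_theta, alpha=config.alpha,
            )
            contrast_df = fit.summary()
            theta = fit.theta
            contrast_df.to_csv(out_dir / "contrast.tsv", sep="\t", index=False,
                               float_format="%.10g")
            logger.info("stage=contrast n=%d events=%d theta=%.4g",
                        fit.n, fit.n_events, fit.theta)
            manifest["stages"]["contrast"] = {
                "n": fit.n, "events": fit.n_events, "theta": fit.theta,
                "converged": fit.converged,
            }
        except ValueError as err:
            logger.warning("stage=contrast skipped: %s", err)
            manifest["stages"]["contrast"] = {"skipped": str(err)}

        stage = "singleton_report"
        report = singleton_vs_family_report(
            scores, pedigrees, tables, persons,
            top_fraction=config.top_fraction, alpha=config.alpha,
        )
        report.to_csv(out_dir / "singleton_report.tsv", sep="\t", index=False,
                      float_format="%.10g")
        logger.info("stage=singleton_report bands=%d", len(report))
        manifest["stages"]["singleton_report"] = {
            "bands": report[["band", "n"]].to_dict("records") if len(report) else [],
        }

        stage = "manifest"
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    except PipelineStageError:
        raise
    except Exception as err:  # noqa: BLE001 - annotate stage and re-raise
        raise PipelineStageError(stage, err) from err
    finally:
        logger.removeHandler(handler)
        handler.close()

    return RunResult(
        out_dir=out_dir,
        scores=scores,
        classification_counts=counts,
        smr_by_bin=smr_by_bin,
        smr_by_label=smr_by_label,
        contrast=contrast_df,
        theta=theta,
        singleton_report=report,
        manifest=manifest,
    )


def _contrast_records(
    pedigrees: list[Pedigree],
    merged: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Assemble case/control (and scheme-B spouse) rows for the contrast."""
    label_by_person = dict(zip(merged["person_id"], merged["label"]))
    rows = []
    for r in merged.itertuples(index=False):
        if r.label not in ("family_case", "family_control"):
            continue
        rows.append(
            {
                "person_id": r.person_id, "family_id": r.family_id,
                "group": r.label, "t": r.t, "event": r.d,
                "birth_year": r.birth_year, "sex": r.sex,
                "n_siblings": r.n_siblings,
            }
        )
    if config.contrast_scheme == "B":
        for ped in pedigrees:
            for p in ped:
                if p.role_tag is None or "spouse" not in p.role_tag.lower():
                    continue
                partner_label = label_by_person.get(p.partner_id)
                if partner_label == "family_case":
                    group = "spouse_of_case"
                elif partner_label == "family_control":
                    group = "spouse_of_control"
                else:
                    continue
                rows.append(
                    {
                        "person_id": p.person_id, "family_id": p.family_id,
                        "group": group,
                        "t": p.age_end if p.age_end is not None else np.nan,
                        "event": 1 if p.vital_status == "dead" else 0,
                        "birth_year": p.birth_year, "sex": p.sex,
                        "n_siblings": len(ped.sibling_ids(p.person_id)),
                    }
                )
    return pd.DataFrame(rows)
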