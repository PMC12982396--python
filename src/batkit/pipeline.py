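"""End-to-end orchestration: generate -> gate -> score -> classify -> associate.

A run is fully determined by one :class:`RunConfig` (one seed): the cohort is
sampled, event tables are simulated and gated per donor x condition, response
profiles are scored and filtered, donors are classified, the expression
layers are simulated from the latent response, and the biomarker statistics
are computed. All intermediate tables are persisted under the output
directory and summarized in a JSON run report with a complete exclusion
audit trail. Re-running with the persisted config echo reproduces every
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from . import io as bio
from .association import roc_analysis, spearman_assoc
from .expression import de_screen, ExpressionError
from .gating import GateConfig, PopulationCounts, count_populations
from .scoring import (
    apply_exclusions, classify_margin, classify_rank_split,
    condition_summaries, profiles_table, response_profile,
)
from .synthetic import (
    CohortConfig, Condition, CONDITIONS, ConfigurationError,
    ExpressionConfig, expected_response, sample_cohort, sample_seed_sequence,
    simulate_ct, simulate_events, simulate_expression,
)
from .expression import ddct_expression

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration problems; carries the full error list in ``errors``."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    gates: GateConfig = field(default_factory=GateConfig)
    classification_method: str = "rank_split"   # rank_split | margin
    margin: float = 0.6
    outdir: str = "batkit_run"
    seed: int = 0
    persist_events: bool = True

    def __post_init__(self) -> None:
        errors = []
        if self.classification_method not in ("rank_split", "margin"):
            errors.append(
                "classification_method: must be 'rank_split' or 'margin'")
        if self.margin <= 0:
            errors.append("margin: must be > 0")
        if errors:
            raise ConfigError(errors)

    def with_seed(self, seed: int) -> "RunConfig":
        """One seed drives every stage's sub-stream."""
        return replace(
            self, seed=seed,
            cohort=replace(self.cohort, seed=seed),
            expression=replace(self.expression, seed=seed),
        )


_NESTED = {
    "cohort": CohortConfig,
    "expression": ExpressionConfig,
    "gates": GateConfig,
}


def config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    """Build a RunConfig from a plain mapping, collecting all field errors."""
    errors: list[str] = []
    kwargs: dict[str, Any] = {}
    data = dict(data)
    classification = data.pop("classification", None)
    if classification is not None:
        kwargs["classification_method"] = classification.get("method",
                                                             "rank_split")
        if "margin" in classification:
            kwargs["margin"] = classification["margin"]
    for section, cls in _NESTED.items():
        payload = data.pop(section, {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            errors.append(f"{section}: unknown fields {sorted(unknown)}")
            payload = {k: v for k, v in payload.items() if k in known}
        payload = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in payload.items()
        }
        try:
            kwargs[section] = cls(**payload)
        except (ConfigurationError, ValueError) as exc:
            errors.append(f"{section}.{exc}")
    for key in ("outdir", "seed", "persist_events",
                "classification_method", "margin"):
        if key in data:
            kwargs[key] = data.pop(key)
    if data:
        errors.append(f"unknown top-level fields: {sorted(data)}")
    if errors:
        raise ConfigError(errors)
    try:
        cfg = RunConfig(**kwargs)
    except ConfigError:
        raise
    return cfg.with_seed(int(kwargs.get("seed", 0)))


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON config file.

    Raises :class:`ConfigError` whose ``errors`` attribute names every
    offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, Mapping):
        raise ConfigError([f"config root must be a mapping, got {type(data)}"])
    return config_from_dict(data)


def config_to_dict(config: RunConfig) -> dict:
    out = dataclasses.asdict(config)
    out["classification"] = {"method": out.pop("classification_method"),
                             "margin": out.pop("margin")}
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _prepare_outdir(outdir: Path, persist_events: bool) -> None:
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
        if persist_events:
            (outdir / "events").mkdir(exist_ok=True)
    except OSError as exc:
        raise ConfigError([f"outdir: not writable ({exc})"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report (also persisted)."""
    outdir = Path(config.outdir)
    _prepare_outdir(outdir, config.persist_events)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    cohort_cfg = config.cohort
    donors = sample_cohort(cohort_cfg)
    log(f"simulate: cohort of {len(donors)} donors (seed {config.seed})")

    # --- gate ---------------------------------------------------------
    counts_by_donor: dict[str, dict[Condition, PopulationCounts]] = {}
    all_counts: list[PopulationCounts] = []
    manifest: dict[str, Any] = {"samples": [], "seed": config.seed,
                                "n_donors": len(donors)}
    for donor in donors:
        counts_by_donor[donor.donor_id] = {}
        for condition in CONDITIONS:
            ss = sample_seed_sequence(config.seed, donor.donor_id, condition)
            events = simulate_events(donor, condition,
                                     cohort_cfg.events_per_sample, ss,
                                     cohort_cfg)
            if config.persist_events:
                path = outdir / "events" / f"{donor.donor_id}_{condition.value}.csv"
                bio.write_events(events, path)
                manifest["samples"].append({
                    "donor_id": donor.donor_id, "condition": condition.value,
                    "path": str(path.relative_to(outdir)),
                    "n_events": len(events),
                })
            pc = count_populations(events, config.gates)
            counts_by_donor[donor.donor_id][condition] = pc
            all_counts.append(pc)
    bio.write_counts(all_counts, outdir / "population_counts.tsv")
    if config.persist_events:
        bio.write_manifest(manifest, outdir / "events" / "manifest.json")
    log(f"gate: {len(all_counts)} samples gated")

    # --- score --------------------------------------------------------
    profiles = [
        response_profile(donor.donor_id,
                         condition_summaries(counts_by_donor[donor.donor_id]))
        for donor in donors
    ]
    profiles, audit = apply_exclusions(profiles)
    n_excluded = sum(1 for p in profiles if p.excluded != "none")
    log(f"score: {len(profiles)} profiles, {n_excluded} excluded")

    if config.classification_method == "margin":
        profiles = classify_margin(profiles, margin=config.margin)
    else:
        profiles = classify_rank_split(profiles)
    bio.write_table(profiles_table(profiles), outdir / "response_profiles.tsv")
    class_counts = profiles_table(profiles)["responder_class"] \
        .value_counts().to_dict()
    log(f"classify ({config.classification_method}): {class_counts}")

    # --- expression layers -------------------------------------------
    expr_cfg = config.expression
    latent_bat_fc = [expected_response(d, cohort_cfg).bat_fc for d in donors]
    counts_matrix = simulate_expression(donors, latent_bat_fc, expr_cfg)
    bio.write_table(counts_matrix, outdir / "expression_counts.tsv", index=True)

    qpcr_genes = list(expr_cfg.reference_genes) + list(expr_cfg.target_genes)
    ct_table = simulate_ct(counts_matrix.loc[qpcr_genes], expr_cfg)
    bio.write_table(ct_table, outdir / "ct_table.tsv")
    rel_expr = ddct_expression(ct_table,
                               target_genes=list(expr_cfg.target_genes),
                               reference_genes=expr_cfg.reference_genes)
    bio.write_table(rel_expr, outdir / "relative_expression.tsv", index=True)
    log(f"expression: {counts_matrix.shape[0]} genes x "
        f"{counts_matrix.shape[1]} samples; qPCR on {len(qpcr_genes)} genes")

    # --- DE screen ----------------------------------------------------
    groups = {p.donor_id: p.responder_class for p in profiles
              if p.responder_class in ("better", "poor_non")}
    de_note = ""
    de_headline: dict[str, Any] = {}
    try:
        de = de_screen(counts_matrix, groups)
        bio.write_table(de, outdir / "de_results.tsv")
        de_headline = {
            "n_significant": int(de["significant"].sum()),
            "n_adj_significant": int(
                ((de["p_adj"] < 0.05) & de["significant"]).sum()),
            "n_tested": int(len(de)),
        }
        log(f"de_screen: {de_headline['n_significant']} genes past "
            "|log2FC|>2 & p<0.05")
    except ExpressionError as exc:
        de_note = str(exc)
        log(f"de_screen skipped: {exc}")

    # --- association --------------------------------------------------
    included = [p for p in profiles if p.included]
    assoc_note = ""
    assoc_rows: list[dict] = []
    roc_headline: dict[str, Any] = {}
    if len(included) >= 4:
        ids = [p.donor_id for p in included
               if p.donor_id in rel_expr.index]
        est_fc = {p.donor_id: p.bat_fc for p in included}
        assoc = spearman_assoc(rel_expr.loc[ids].T,
                               [est_fc[i] for i in ids])
        bio.write_table(assoc, outdir / "association.tsv")
        assoc_rows = assoc.to_dict(orient="records")
        labels = [1 if groups.get(i) == "better" else 0 for i in ids]
        if 0 < sum(labels) < len(labels):
            roc = roc_analysis(rel_expr.loc[ids, "RSAD2"].to_numpy(), labels)
            bio.write_table(roc.thresholds, outdir / "roc_thresholds.tsv")
            roc_headline = {"auc": roc.auc, "ci": [roc.ci_low, roc.ci_high],
                            "n_positive": roc.n_positive,
                            "n_negative": roc.n_negative}
            log(f"roc: RSAD2 AUC {roc.auc:.3f}")
        else:
            assoc_note = "single-class cohort; ROC skipped"
            log("roc skipped: only one responder class present")
    else:
        assoc_note = "fewer than 4 included donors; association skipped"
        log("association skipped: fewer than 4 included donors")

    report = {
        "software": {"name": "batkit", "version": __version__},
        "seed": config.seed,
        "config": config_to_dict(config),
        "stages": {
            "cohort": {"n_donors": len(donors)},
            "gating": {"n_samples": len(all_counts)},
            "scoring": {"n_profiles": len(profiles),
                        "n_excluded": n_excluded},
            "classification": {"method": config.classification_method,
                               "counts": class_counts},
            "de_screen": de_headline or {"skipped": de_note},
            "association": {"rows": assoc_rows, "roc": roc_headline,
                            "note": assoc_note},
        },
        "exclusion_audit": audit,
    }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float) + "\n")
    (outdir / "config_echo.yaml").write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=True))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
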