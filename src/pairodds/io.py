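"""Read survey data and drive the whole pipeline.

The canonical input is CSV, either *wide* (one row per survey, one 0/1
column per species, plus optional site / survey-identifier / metadata
columns) or *long* (site, survey, species triples; combinations not
listed are absences). :func:`run_pipeline` chains
filter -> estimate -> assemble -> layout -> render and writes node and
edge tables, GraphML, diagram files, the layout coordinates and a
machine-readable manifest (configuration, seed, versions, per-stage
counts and output checksums) so a run can be reproduced and compared.
A saved layout can be reused across subset runs so, e.g., two habitats
are drawn with identical node positions for side-by-side comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assemble import AssemblyConfig, AssociationNetwork, classify_edges, filter_by_prevalence
from .estimation import PairEstimate, SurveyTable, estimate_all_pairs, estimates_to_frame
from .viz import DiagramStyle, layout_nodes, load_layout, render_diagram, save_layout

__all__ = ["RunConfig", "RunResult", "read_survey_csv", "run_pipeline"]

log = logging.getLogger("pairodds")


def _parse_subset(subset: str | None) -> tuple[str, str] | None:
    if subset is None:
        return None
    if "=" not in subset:
        raise ValueError(f"subset must look like COLUMN=VALUE, got {subset!r}")
    col, val = subset.split("=", 1)
    return col.strip(), val.strip()


def read_survey_csv(
    path,
    format: str = "wide",
    site_column: str = "site",
    survey_column: str = "survey",
    species_column: str = "species",
    subset: str | None = None,
    ignore_columns: tuple[str, ...] = (),
) -> SurveyTable:
    """Load a survey x species presence table from CSV.

    Wide format: every column other than the site / survey-identifier /
    ignored columns is a species with 0/1 entries. Long format: one row
    per (site, survey, species) presence record; absent combinations are
    zeros. ``subset="COLUMN=VALUE"`` keeps only matching surveys (the
    column is compared as text and not treated as a species).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} is empty: no survey data to read") from None
    if frame.empty:
        raise ValueError(f"{path} contains no survey rows")

    pred = _parse_subset(subset)
    drop = set(ignore_columns)
    if pred is not None:
        col, val = pred
        if col not in frame.columns:
            raise ValueError(f"subset column {col!r} not present in {path}")
        frame = frame[frame[col].astype(str) == val]
        if frame.empty:
            raise ValueError(f"subset {subset!r} matches no surveys in {path}")
        drop.add(col)

    if format == "wide":
        sites = None
        if site_column in frame.columns:
            sites = frame[site_column]
            drop.add(site_column)
        if survey_column in frame.columns:
            if frame[survey_column].duplicated().any():
                dup = frame[survey_column][frame[survey_column].duplicated()].iloc[0]
                raise ValueError(f"duplicate survey identifier {dup!r} in {path}")
            frame = frame.set_index(survey_column)
            if sites is not None:
                sites = sites.set_axis(frame.index)
        species = frame.drop(columns=[c for c in drop if c in frame.columns])
        # columns with no 0/1 values at all are metadata (habitat labels,
        # years, ...) and are set aside; a stray non-binary entry in an
        # otherwise binary column is still an error (handled downstream).
        meta = [
            col
            for col in species.columns
            if not species[col].isin((0, 1, "0", "1")).any()
        ]
        if meta:
            log.warning("ignoring non-presence columns: %s", ", ".join(map(str, meta)))
            species = species.drop(columns=meta)
        if species.shape[1] == 0:
            raise ValueError(f"{path} has no species columns")
        try:
            return SurveyTable(species, sites=sites)
        except ValueError as err:  # add file context (header is line 1)
            raise ValueError(f"{path}: {err}") from None

    if format == "long":
        needed = [site_column, survey_column, species_column]
        missing = [c for c in needed if c not in frame.columns]
        if missing:
            raise ValueError(f"{path} lacks long-format columns {missing}")
        value = pd.Series(1, index=frame.index)
        if "value" in frame.columns:
            value = frame["value"]
        wide = (
            pd.DataFrame(
                {
                    "survey": frame[survey_column],
                    "species": frame[species_column],
                    "value": value,
                }
            )
            .pivot_table(index="survey", columns="species", values="value", fill_value=0)
            .astype(int)
        )
        site_of = frame.drop_duplicates(survey_column).set_index(survey_column)[site_column]
        if frame.groupby(survey_column)[site_column].nunique().max() > 1:
            raise ValueError(f"{path}: a survey maps to more than one site")
        wide = wide.sort_index()
        try:
            return SurveyTable(wide, sites=site_of.reindex(wide.index))
        except ValueError as err:
            raise ValueError(f"{path}: {err}") from None

    raise ValueError(f"format must be 'wide' or 'long', got {format!r}")


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    input: str = ""
    format: str = "wide"
    site_column: str = "site"
    survey_column: str = "survey"
    species_column: str = "species"
    subset: str | None = None
    estimator: str = "raw"
    prevalence_min: float = 0.10
    or_upper: float = 3.0
    or_lower: float | None = None  # defaults to 1 / or_upper
    alpha: float = 0.05
    multiplicity: str = "bonferroni_by_species"
    ci_level: float = 0.95
    style: dict = field(default_factory=dict)
    layout_in: str | None = None
    layout_out: str | None = None
    outdir: str = "pairodds_out"
    seed: int = 0
    quiet: bool = False

    def assembly_config(self) -> AssemblyConfig:
        lower = self.or_lower if self.or_lower is not None else 1.0 / self.or_upper
        return AssemblyConfig(
            prevalence_min=self.prevalence_min,
            or_upper=self.or_upper,
            or_lower=lower,
            alpha=self.alpha,
            multiplicity=self.multiplicity,
            ci_level=self.ci_level,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunResult:
    data: SurveyTable
    filtered: SurveyTable
    filter_report: pd.DataFrame
    estimates: list[PairEstimate]
    network: AssociationNetwork
    positions: dict
    manifest: dict
    outdir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute filter -> estimate -> assemble -> layout -> render.

    Writes ``nodes.csv``, ``edges.csv`` (directed edge list in the style
    of a published odds-ratio table), ``estimates.csv`` (every pair,
    classified or not), ``network.graphml``, ``diagram.svg``/``.png``,
    ``layout.csv`` and ``manifest.json`` into ``config.outdir``. Any
    stage failure aborts with the stage named in the error.
    """
    if not config.quiet:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO, force=False)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        data = read_survey_csv(
            config.input,
            format=config.format,
            site_column=config.site_column,
            survey_column=config.survey_column,
            species_column=config.species_column,
            subset=config.subset,
        )
        log.info("read %d surveys x %d species", data.n_surveys, data.n_species)

        stage = "filter"
        filtered, report = filter_by_prevalence(data, config.prevalence_min)
        log.info(
            "prevalence filter at %.0f%%: %d retained, %d dropped",
            100 * config.prevalence_min, filtered.n_species, len(report),
        )

        stage = "estimate"
        estimates = estimate_all_pairs(
            filtered, estimator=config.estimator, ci_level=config.ci_level
        )
        boundary = sum(e.status == "boundary" for e in estimates)
        if boundary:
            log.warning("%d pair estimates are boundary fits (OR 0 or infinite)", boundary)

        stage = "assemble"
        network = classify_edges(
            estimates,
            config.assembly_config(),
            prevalences=filtered.prevalence(),
            estimator=config.estimator,
        )
        log.info(
            "network: %d indications, %d contraindications",
            network.n_indications, network.n_contraindications,
        )

        stage = "layout"
        fixed = load_layout(config.layout_in) if config.layout_in else None
        positions = layout_nodes(network, seed=config.seed, fixed_positions=fixed)
        save_layout(positions, outdir / "layout.csv")
        if config.layout_out:
            save_layout(positions, config.layout_out)

        stage = "render"
        style = DiagramStyle(**config.style)
        render_diagram(network, positions, style, outdir / "diagram.svg")
        render_diagram(network, positions, style, outdir / "diagram.png")

        stage = "write"
        network.node_frame().to_csv(outdir / "nodes.csv", index=False)
        network.edge_frame().to_csv(outdir / "edges.csv", index=False)
        estimates_to_frame(estimates).to_csv(outdir / "estimates.csv", index=False)
        network.to_graphml(outdir / "network.graphml")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {
            "pairodds": __version__,
            "python": sys.version.split()[0],
            "numpy": __import__("numpy").__version__,
            "pandas": pd.__version__,
        },
        "counts": {
            "surveys": data.n_surveys,
            "sites": data.n_sites,
            "species_in": data.n_species,
            "species_retained": filtered.n_species,
            "species_dropped": len(report),
            "estimates": len(estimates),
            "edges": len(network.edges),
            "indications": network.n_indications,
            "contraindications": network.n_contraindications,
        },
        "outputs": {
            name: _sha256(outdir / name)
            for name in (
                "nodes.csv", "edges.csv", "estimates.csv",
                "network.graphml", "layout.csv", "diagram.svg",
            )
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunResult(
        data=data,
        filtered=filtered,
        filter_report=report,
        estimates=estimates,
        network=network,
        positions=positions,
        manifest=manifest,
        outdir=outdir,
    )
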