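"""Shared fixtures: one reference-fixture pipeline run per test session."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

from airmark import grouping, msp_io
from airmark.cli import RunConfig, run_pipeline
from airmark.markers import ComparisonReport, blank_filter
from airmark.msp_io import SampleManifest
from airmark.synthfix import generate_fixture, reference_design


@dataclass
class ReferenceRun:
    """Everything the end-to-end tests need from one seed-1 pipeline run."""

    design: object
    manifest: SampleManifest
    tables: dict[str, grouping.GroupTable]  # finalized + blank-filtered
    reports: dict[str, ComparisonReport]
    out_dir: Path
    spiked_names: frozenset[str]


def _build_tables(manifest: SampleManifest) -> dict[str, grouping.GroupTable]:
    tables: dict[str, grouping.GroupTable] = {}
    for group in manifest.groups:
        table = grouping.GroupTable(group=group)
        for entry in manifest.entries_for(group):
            grouping.merge_sample(table, msp_io.parse_msp(entry.path), entry.sample_id)
        grouping.finalize_group(table)
        tables[group] = table
    blank = tables[manifest.blank_group]
    for group in manifest.groups:
        if group != manifest.blank_group:
            blank_filter(tables[group], blank)
    return tables


@pytest.fixture(scope="session")
def reference_run(tmp_path_factory) -> ReferenceRun:
    base = tmp_path_factory.mktemp("reference_run")
    design = reference_design(seed=1)
    manifest = generate_fixture(design, base / "fixture")
    reports = run_pipeline(manifest, RunConfig(), base / "results")
    tables = _build_tables(manifest)
    return ReferenceRun(
        design=design,
        manifest=manifest,
        tables=tables,
        reports=reports,
        out_dir=base / "results",
        spiked_names=frozenset(c.name for c in design.compounds),
    )
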