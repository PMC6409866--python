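"""Shared fixtures: all test data is generated programmatically.

The expensive fixture is a 200-nucleus two-cohort population mimicking the
standard experimental design (chrX/chrY co-hybridised at a shared
dorsal/sub-acrosomal address; chr11/chr19 placed independently within a
shared ventral/basal region). It is built once per session and reused by
the end-to-end and acceptance tests.
"""

from __future__ import annotations

import pytest

import nucleocarta as nc
from nucleocarta.cli import (
    AnalysisOptions,
    build_template,
    detect_population,
    warp_population,
)


@pytest.fixture(scope="session")
def calibration():
    return nc.Calibration(0.05)


@pytest.fixture(scope="session")
def single_nucleus(calibration):
    """One default pre-oriented nucleus with its counterstain raster."""
    placed, raster = nc.generate_nucleus(seed=11, calibration=calibration)
    return placed, raster


@pytest.fixture(scope="session")
def detected_outline(single_nucleus, calibration):
    """The segmented outline of the single fixture nucleus."""
    placed, raster = single_nucleus
    field = nc.FieldImage({"counterstain": raster}, calibration)
    outlines = nc.detect_nuclei(field)
    assert len(outlines) == 1
    return outlines[0]


@pytest.fixture(scope="session")
def small_population():
    """24 nuclei over 3 strains with an X/Y-style co-located probe pair."""
    signals = [
        nc.PlantedSignal("chrX", "dorsal_subacrosomal"),
        nc.PlantedSignal("chrY", "dorsal_subacrosomal"),
    ]
    fields, manifest = nc.generate_population(
        n_per_strain=8, signals=signals, seed=42
    )
    return fields, manifest


@pytest.fixture(scope="session")
def small_records(small_population):
    fields, _ = small_population
    return detect_population(fields)


XY_SIGNALS = [
    nc.PlantedSignal("chrX", "dorsal_subacrosomal", placement_noise=0.05),
    nc.PlantedSignal("chrY", "dorsal_subacrosomal", placement_noise=0.05),
]
# chr11/chr19 drawn independently from one broader ventral/basal region
AUTO_SIGNALS = [
    nc.PlantedSignal("chr11", "ventral_basal", placement_noise=0.05, u_sd=0.10, v_sd=0.20),
    nc.PlantedSignal("chr19", "ventral_basal", placement_noise=0.05, u_sd=0.10, v_sd=0.20),
]


@pytest.fixture(scope="session")
def cohort_population():
    """Two 100-nucleus cohorts: X+Y and 11+19 co-hybridisations."""
    fields_xy, man_xy = nc.generate_population(
        strains=nc.DEFAULT_STRAINS[:1], n_per_strain=100, signals=XY_SIGNALS, seed=101
    )
    fields_auto, man_auto = nc.generate_population(
        strains=nc.DEFAULT_STRAINS[:1], n_per_strain=100, signals=AUTO_SIGNALS, seed=202
    )
    return (fields_xy, man_xy), (fields_auto, man_auto)


@pytest.fixture(scope="session")
def cohort_composites(cohort_population):
    """Per-probe composite maps of the two cohorts on one common template."""
    (fields_xy, _), (fields_auto, _) = cohort_population
    opts = AnalysisOptions()
    recs_xy = detect_population(fields_xy, opts)
    recs_auto = detect_population(fields_auto, opts)
    _, template = build_template(recs_xy + recs_auto, opts)
    warps_xy = warp_population(fields_xy, recs_xy, template, opts)
    warps_auto = warp_population(fields_auto, recs_auto, template, opts)
    comps = {
        "chrX": nc.composite(warps_xy["signal_A"], "chrX"),
        "chrY": nc.composite(warps_xy["signal_B"], "chrY"),
        "chr11": nc.composite(warps_auto["signal_A"], "chr11"),
        "chr19": nc.composite(warps_auto["signal_B"], "chr19"),
    }
    return {
        "composites": comps,
        "template": template,
        "records": {"xy": recs_xy, "auto": recs_auto},
        "fields": {"xy": fields_xy, "auto": fields_auto},
    }
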