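"""Shared fixtures: small baths and phantom cavities with analytic truth.

Everything is generated programmatically at session scope so the expensive
geometry (bath packing, Voronoi tessellation, alpha-shape surfacing) is done
once and reused across test modules.
"""

import numpy as np
import pytest

from voidshape import (
    ExtractionParameters,
    build_surface,
    compute_probe_spheres,
    generate_water_bath,
    make_phantom_frame,
    merge_probes,
    select_host_void,
)


@pytest.fixture(scope="session")
def small_bath():
    """Pure water bath, 20 A box at ambient density."""
    return generate_water_bath(20.0, 33.4, seed=11)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Carved + wall-lined spherical cavity, r = 4 A, with truth."""
    return make_phantom_frame("sphere", 4.0, box_side=24.0, seed=42)


@pytest.fixture(scope="session")
def sphere_analysis(sphere_phantom):
    """(frame, truth, graph, voids, host, surface) for the sphere phantom."""
    frame, truth = sphere_phantom
    params = ExtractionParameters()
    graph = compute_probe_spheres(frame.without_solute(), params)
    voids = merge_probes(graph, params)
    host = select_host_void(voids, frame.solute_pos, frame.solute_radii,
                            graph)
    surface = build_surface(host, graph)
    return frame, truth, graph, voids, host, surface


@pytest.fixture(scope="session")
def star_phantom():
    """Star cavity with 3 tendrils of 8 A, with truth."""
    return make_phantom_frame("star", 4.0, n_tendrils=3, tendril_length=8.0,
                              box_side=30.0, seed=13)


@pytest.fixture(scope="session")
def star_analysis(star_phantom):
    frame, truth = star_phantom
    params = ExtractionParameters()
    graph = compute_probe_spheres(frame.without_solute(), params)
    voids = merge_probes(graph, params)
    host = select_host_void(voids, frame.solute_pos, frame.solute_radii,
                            graph)
    surface = build_surface(host, graph)
    return frame, truth, graph, voids, host, surface
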