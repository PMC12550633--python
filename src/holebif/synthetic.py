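"""Random and perturbed landscapes for testing and optimizer seeding.

The generators keep a template's topology fixed and resample its energetic
and geometric parameters: relay/terminus potentials drawn uniformly within
bounds and edge distances drawn uniformly within bounds, mirroring the
box-bounded design space the Bayesian optimizer searches.  Bifurcation-site
potentials are left at the template value (they are set by the chemistry of
the dimer, not by design placement).  All sampling is uniform and every
generator takes an explicit seed.
"""

from __future__ import annotations

import numpy as np

from .landscape import Landscape, fig8_landscape

__all__ = ["random_landscape", "perturbed_fig8"]


def _check_bounds(name: str, bounds) -> tuple:
    lo, hi = float(bounds[0]), float(bounds[1])
    if hi < lo:
        raise ValueError(f"{name} bounds are inverted: ({lo}, {hi})")
    return lo, hi


def random_landscape(
    template: Landscape,
    potential_bounds,
    distance_bounds,
    seed: int,
) -> Landscape:
    """Template topology with uniformly resampled potentials and distances.

    Every relay and terminus potential is drawn uniformly from
    ``potential_bounds`` (V) and every edge distance from
    ``distance_bounds`` (angstrom); zero-width bounds return the bound
    value.  Deterministic for a fixed seed.
    """
    plo, phi = _check_bounds("potential", potential_bounds)
    dlo, dhi = _check_bounds("distance", distance_bounds)
    rng = np.random.default_rng(seed)
    potentials = {
        c.id: float(rng.uniform(plo, phi))
        for c in template.cofactors
        if c.role != "bifurcation_site"
    }
    distances = {e.pair: float(rng.uniform(dlo, dhi)) for e in template.edges}
    return template.with_overrides(potentials=potentials, distances=distances)


def perturbed_fig8(
    noise_scale_potential: float = 0.02,
    noise_scale_distance: float = 0.25,
    seed: int = 0,
    epsilon: float = 1.6,
) -> Landscape:
    """Canonical design with additive uniform jitter.

    Relay/terminus potentials receive uniform noise in
    ``+-noise_scale_potential`` (V) and edge distances uniform noise in
    ``+-noise_scale_distance`` (angstrom); zero scales reproduce the
    fixture exactly.  Used to map the high-yield basin around the design.
    """
    if noise_scale_potential < 0 or noise_scale_distance < 0:
        raise ValueError("noise scales must be >= 0")
    base = fig8_landscape(epsilon=epsilon)
    rng = np.random.default_rng(seed)
    potentials = {
        c.id: c.potential + float(rng.uniform(-noise_scale_potential, noise_scale_potential))
        for c in base.cofactors
        if c.role != "bifurcation_site"
    }
    distances = {
        e.pair: max(
            e.distance + float(rng.uniform(-noise_scale_distance, noise_scale_distance)),
            0.1,
        )
        for e in base.edges
    }
    return base.with_overrides(potentials=potentials, distances=distances)
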