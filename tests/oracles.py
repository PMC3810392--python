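"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's finite-volume machinery: the channel
uptake oracle marches the parabolized advection–diffusion equation (axial
diffusion neglected) down a plane channel with an analytic Poiseuille
profile, on its own fine cross-channel grid.
"""

import numpy as np
import scipy.linalg as sla


def marching_uptake(h: float, length: float, u_mean: float, diffusivity: float,
                    k_m: float, ny: int = 128, nx: int = 3000) -> float:
    """Fraction of the odorant mass flux absorbed by the two Robin walls of a
    plane channel of gap ``h`` over ``length``, for fully developed laminar
    flow with mean speed ``u_mean``.

    Implicit (backward-Euler) marching in x on a ``ny``-point wall-normal
    grid; the Robin wall is the series resistance of the mucus film (1/k_m)
    and the half-cell air gap.
    """
    dy = h / ny
    y = (np.arange(ny) + 0.5) * dy
    u = 1.5 * u_mean * (1.0 - (2.0 * y / h - 1.0) ** 2)
    dx = length / nx
    c = np.ones(ny)
    main = u / dx + 2.0 * diffusivity / dy ** 2
    a_wall = 0.0 if k_m == 0 else 1.0 / (1.0 / k_m + 0.5 * dy / diffusivity)
    main[0] += a_wall / dy - diffusivity / dy ** 2
    main[-1] += a_wall / dy - diffusivity / dy ** 2
    ab = np.zeros((3, ny))
    ab[0, 1:] = -diffusivity / dy ** 2
    ab[1, :] = main
    ab[2, :-1] = -diffusivity / dy ** 2
    flux_in = float((u * c).sum() * dy)
    for _ in range(nx):
        c = sla.solve_banded((1, 1), ab, u / dx * c)
    return 1.0 - float((u * c).sum() * dy) / flux_in
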