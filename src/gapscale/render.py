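"""Schematic pseudo-microscopy renderer.

Draws a mid-sagittal embryo view with three channels: a nuclear (DAPI-like)
channel carrying a dim cytoplasmic background plus a dorsal row of nuclear
blobs whose length and spacing encode the time class; a FISH-like channel
modulated along AP by one gene's expression profile; and a DIC-proxy
channel encoding the dorsal membrane invagination as a vertical ridge whose
depth relative to the embryo half-height equals the invagination ratio.

The embryo mask is a horizontal superellipse with a blunter anterior end
(larger exponent) so the orientation heuristic of :mod:`gapscale.imaging`
has something to grab.  Fidelity target is extractor-recoverable geometry,
not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RenderConfig, StagingConfig


class RenderError(ValueError):
    pass


@dataclass
class EmbryoImage:
    """Rendered 2-D channels sharing one shape; anterior left, dorsal up."""

    nuclear_channel: np.ndarray
    fish_channel: np.ndarray
    dic_proxy_channel: np.ndarray
    pixel_size_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (
            self.nuclear_channel.shape
            == self.fish_channel.shape
            == self.dic_proxy_channel.shape
        ):
            raise RenderError("channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclear_channel.shape


def _superellipse_halfheight(
    u: np.ndarray, b: float, p_ant: float, p_post: float
) -> np.ndarray:
    """Half-height profile over signed normalised AP coordinate u in [-1, 1];
    anterior (u < 0) uses the blunter exponent."""
    h = np.zeros_like(u)
    inside = np.abs(u) <= 1.0
    p = np.where(u < 0, p_ant, p_post)
    h[inside] = b * (1.0 - np.abs(u[inside]) ** p[inside]) ** (1.0 / p[inside])
    return h


def render_embryo_image(
    length_um: float,
    time_class: str,
    gene_profile: np.ndarray,
    invagination_ratio: float,
    staging: StagingConfig | None = None,
    render: RenderConfig | None = None,
    metadata: dict | None = None,
) -> EmbryoImage:
    """Render one embryo.

    Parameters
    ----------
    gene_profile
        50-bin (or longer) expression profile on [0, 1]; the FISH channel
        is this profile interpolated at each pixel's fractional AP
        position, constant dorsoventrally within the mask.
    invagination_ratio
        True invagination depth as a fraction of the dorsal half-height.

    Raises
    ------
    RenderError
        If the resolution leaves fewer than 2 pixels per AP bin.
    """
    staging = staging or StagingConfig()
    render = render or RenderConfig()
    px = render.pixel_size_um
    L_px = length_um / px
    if L_px < render.min_length_px:
        raise RenderError(
            f"embryo of {length_um:.0f} um at {px} um/px spans {L_px:.0f} px;"
            f" need >= {render.min_length_px} to resolve 50 AP bins"
        )
    a = L_px / 2.0
    b = render.half_height_frac * L_px
    m = render.margin_px
    W = int(np.ceil(L_px)) + 2 * m
    H = int(np.ceil(2 * b)) + 2 * m
    cx, cy = m + a, H / 2.0

    xs = np.arange(W, dtype=float)
    ys = np.arange(H, dtype=float)
    X, Y = np.meshgrid(xs, ys)
    u = (X - cx) / a
    h = _superellipse_halfheight(u, b, render.anterior_exponent,
                                 render.posterior_exponent)
    mask = (np.abs(u) <= 1.0) & (np.abs(Y - cy) <= h)

    # FISH channel: profile along AP, flat dorsoventrally
    xi_of_x = np.clip((xs - (cx - a)) / (2 * a), 0.0, 1.0)
    nb = len(gene_profile)
    centers = (np.arange(nb) + 0.5) / nb
    fish_line = np.interp(xi_of_x, centers, np.asarray(gene_profile, float))
    fish = np.where(mask, render.fish_base + fish_line[None, :], 0.0)

    # nuclear channel: cytoplasmic base + dorsal blob row
    nuclear = np.where(mask, render.nuclear_base, 0.0)
    if time_class == "nc13":
        nl, spacing = staging.nc13_nuclear_length, staging.nc13_internuclear
    else:
        nl = staging.nc14_nuclear_length[time_class]
        spacing = staging.nc14_internuclear
    nl_px, sp_px = nl / px, spacing / px
    wx_px = min(render.nuclear_blob_width_um / px, 0.8 * sp_px)
    # blob centres along the dorsal edge, skipping the sharply curved poles
    n_side = int(0.85 * a / sp_px)
    xk = cx + sp_px * np.arange(-n_side, n_side + 1)
    uk = (xk - cx) / a
    hk = _superellipse_halfheight(uk, b, render.anterior_exponent,
                                  render.posterior_exponent)
    yk = cy - hk + nl_px / 2.0 + 1.0  # just inside the dorsal edge
    c = 4.0 * np.log(2.0)
    for x0, y0 in zip(xk, yk):
        # local patch only; Gaussian with FWHM (wx, nl)
        x_lo = max(int(x0 - 3 * wx_px), 0)
        x_hi = min(int(x0 + 3 * wx_px) + 1, W)
        y_lo = max(int(y0 - 3 * nl_px), 0)
        y_hi = min(int(y0 + 3 * nl_px) + 1, H)
        gx = np.exp(-c * ((xs[x_lo:x_hi] - x0) / wx_px) ** 2)
        gy = np.exp(-c * ((ys[y_lo:y_hi] - y0) / nl_px) ** 2)
        nuclear[y_lo:y_hi, x_lo:x_hi] = np.maximum(
            nuclear[y_lo:y_hi, x_lo:x_hi], np.outer(gy, gx)
        )
    nuclear = np.where(mask, nuclear, 0.0)

    # DIC proxy: vertical invagination ridge at mid-AP, depth = ratio * b
    dic = np.zeros((H, W))
    if invagination_ratio > 0:
        depth_px = int(round(invagination_ratio * b))
        x_mid = int(round(cx))
        y_top = int(np.ceil(cy - b))
        dic[y_top : y_top + depth_px, x_mid - 1 : x_mid + 2] = 1.0

    md = dict(metadata or {})
    md.update(
        time_class=time_class,
        length_um=length_um,
        invagination_ratio=invagination_ratio,
        nuclear_length_um=nl,
        internuclear_um=spacing,
    )
    return EmbryoImage(nuclear, fish, dic, px, md)


def render_cohort_images(cohort, genes=None, embryo_ids=None):
    """Yield ``(embryo_row, gene, EmbryoImage)`` for embryos of a cohort.

    ``genes`` may be a single gene name, a list (cycled across embryos), or
    None for cycling all six.  Profiles must have been generated.
    """
    from .registry import GENES

    if cohort.profiles is None:
        raise ValueError("cohort was generated without profiles")
    if genes is None:
        genes = list(GENES)
    elif isinstance(genes, str):
        genes = [genes]
    prof = cohort.profiles
    emb = cohort.truth.embryos
    if embryo_ids is not None:
        emb = emb[emb.embryo_id.isin(embryo_ids)]
    for i, (_, row) in enumerate(emb.iterrows()):
        gene = genes[i % len(genes)]
        y = (
            prof[(prof.embryo_id == row.embryo_id) & (prof.gene == gene)]
            .sort_values("bin_index")
            .intensity.to_numpy()
        )
        img = render_embryo_image(
            row.length_um,
            row.time_class,
            y,
            row.invagination_ratio,
            staging=cohort.config.staging,
            render=cohort.config.render,
            metadata={"embryo_id": row.embryo_id, "gene": gene},
        )
        yield row, gene, img
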