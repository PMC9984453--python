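"""Monte-Carlo Bcd threshold model: Delta-xi^B for the two pairs.

Simulates 10,000 noisy Bcd gradients per line, reads out threshold
crossings over 50 thresholds indexed by AP position, and prints the
anterior mean Bcd-encoded positional difference for each pair.
"""

import gapscale as gs
from gapscale.bcdmodel import anterior_delta_xi_b, delta_xi_b, pair_ensembles

cfg = gs.default_config()
for pair in cfg.pairs:
    ens_large, ens_small = pair_ensembles(
        pair.line_large, pair.line_small, n=10_000, seed=7
    )
    table = delta_xi_b(ens_large, ens_small)
    mean_ant, sd_ant = anterior_delta_xi_b(table, xi_cut=0.3)
    print(f"{pair.name}: A_L/A_S = "
          f"{pair.line_large.bcd_amplitude / pair.line_small.bcd_amplitude:.3f}, "
          f"(lambda/L)_L = "
          f"{pair.line_large.bcd_length_constant_um / pair.line_large.mean_length_um:.3f}, "
          f"(lambda/L)_S = "
          f"{pair.line_small.bcd_length_constant_um / pair.line_small.mean_length_um:.3f}")
    print(f"  anterior (xi < 0.3) Delta-xi^B = {mean_ant:+.3f} +- {sd_ant:.3f}")
    row = table.iloc[(table.xi_encoded - 0.5).abs().argmin()]
    print(f"  near mid-embryo (xi ~ {row.xi_encoded:.2f}): "
          f"Delta-xi^B = {row.delta_xi_b:+.4f}\n")
# The amplitude-scaled pair encodes anterior positions more posteriorly in
# large embryos (positive Delta-xi^B, over-scaled); the length-constant
# pair the opposite; both vanish near mid-embryo where the gradients are
# configured to scale.
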