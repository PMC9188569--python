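"""Light-driven expression: simulate a characterization run and refit.

Simulates the two-variable EL222 circuit model under three ON-OFF light
programs sampled every 45 min and recovers the three kinetic parameters
by joint bounded least squares (translation rate tied to mRNA decay).
"""

from reacloop.expression import ExpressionParams
from reacloop.workflows import characterization_fit, measured_half_life

truth = ExpressionParams(gamma_m=2.09, sigma=0.64, gamma_fp=0.475)
result = characterization_fit(truth, seed=0)

print("generating parameters:  gamma_m=2.09 h^-1, sigma=0.64 RPU/h, gamma_fp=0.475 h^-1")
print(
    f"recovered parameters:   gamma_m={result.params.gamma_m:.4g} h^-1, "
    f"sigma={result.params.sigma:.4g} RPU/h, gamma_fp={result.params.gamma_fp:.4g} h^-1"
)
print(f"residual cost: {result.cost:.2e}  (noise-free data -> ~0)")
print(
    f"measured half-lives: mRNA {measured_half_life(truth, 'mrna') * 60:.1f} min, "
    f"protein {measured_half_life(truth, 'fp'):.2f} h"
)
print("The fit is exact on noise-free data; half-lives follow ln2/rate "
      "(~20 min for mRNA, 1.46 h for the protein, i.e. mostly dilution).")
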