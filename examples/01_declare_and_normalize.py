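"""Declare a predator-prey structure and derive its generalized Jacobian.

Builds the model from scratch: prey X with reproduction S(X), predation
loss F(X, Y) and other mortality L(X); predator Y with predation gain
G(X, Y) and mortality M(Y).  Normalization moves the unknown steady
state to the all-ones point and parameterizes the Jacobian with a
turnover ratio (alpha_y), a branching weight (sigma_f = share of prey
loss due to predation) and one elasticity per declared dependency.
"""

from genmod import GeneralizedModel, build_jacobian

model = (
    GeneralizedModel()
    .add_variable("X", "prey")
    .add_variable("Y", "predator")
    .add_process("S", [("X", "gain")], ["X"])        # reproduction: no predator effect
    .add_process("F", [("X", "loss")], ["X", "Y"])   # predation loss
    .add_process("L", [("X", "loss")], ["X"])        # other mortality
    .add_process("G", [("Y", "gain")], ["X", "Y"])   # predation gain
    .add_process("M", [("Y", "loss")], ["Y"])        # predator mortality
)
print("validation report:", model.validate() or "clean")

jac = build_jacobian(model, timescale_reference="X")
print("\ngeneralized Jacobian (time in prey-turnover units):")
print(jac.to_text())
print("\nfree parameters:", ", ".join(s.name for s in jac.free_symbols))
# Each entry is linear in the elasticities; sigma_f is the fraction of
# prey loss due to predation, alpha_y the predator/prey turnover ratio.
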