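"""Where in the tissue is the free chemical maximal?

Sweeps the removal rate lambda3 at fixed fast breakdown (lambda2 = 50)
and classifies each steady profile.  Slow removal puts the maximum at the
tissue centre; intermediate removal moves it to an interior point; fast
removal leaves a profile that only decays away from the boundary - the
classical penetration problem the complex-delivery mechanism is meant to
beat.
"""

from tissuetarget import regime_transitions, sweep_lambda3

sweep = sweep_lambda3()
transitions = regime_transitions(sweep)
for name, (lo, hi) in transitions.items():
    print(f"{name}: between lambda3 = {lo:.4f} and {hi:.4f}")
print(
    "\nAt lambda2 = 50 the centre-maximum regime survives only up to\n"
    "lambda3 ~ 0.04: targeting the tissue core requires removal of the\n"
    "active chemical to be much slower than breakdown of its carrier."
)
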