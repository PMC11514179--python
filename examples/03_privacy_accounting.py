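"""Differential-privacy accounting for generator training.

Calibrates the DP-SGD noise multiplier to an epsilon = 1 budget and shows
the conservative PATE composition bound.
"""
from synthcohort.accounting import calibrate_sigma, compose_pate, epsilon_dpsgd

q, steps, delta = 128 / 4000, 30 * (4000 // 128), 1 / 4000
sigma = calibrate_sigma(q, steps, delta, target_epsilon=1.0)
print(f"DP-SGD: sampling rate {q:.3f}, {steps} steps, delta {delta:.2e}")
print(f"calibrated noise multiplier sigma = {sigma:.2f}")
print(f"epsilon actually spent: {epsilon_dpsgd(q, sigma, steps, delta):.4f} <= 1.0")
print(f"half the steps would cost {epsilon_dpsgd(q, sigma, steps // 2, delta):.4f}")

lam = 1e-4
print(f"\nPATE: each noisy-vote query is 2*lambda-DP (lambda = {lam})")
print(f"5000 labeled samples cost epsilon = {compose_pate(lam, 5000):.2f} "
      "(basic composition, a conservative upper bound)")
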