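"""Fit the Poisson droplet-occupancy model and predict pairing efficiency.

Simulates droplet occupancy counts at the bead and semibulk loading rates
used on the real device (λ = 0.66 and 0.03), refits λ from the counted
categories, and multiplies the two rates into the expected probability
that a droplet pairs exactly one bead with one semibulk.
"""

import semibulk as sb

bead_table = sb.simulate_occupancy(lambda_value=0.66, n_droplets=100_000, seed=1)
semibulk_table = sb.simulate_occupancy(lambda_value=0.03, n_droplets=100_000, seed=2)

bead_fit = sb.fit_lambda(bead_table, method="least_squares")
semibulk_fit = sb.fit_lambda(semibulk_table, method="least_squares")
print(f"fitted lambda (beads):     {bead_fit.lambda_hat:.4f}")
print(f"fitted lambda (semibulks): {semibulk_fit.lambda_hat:.4f}")

fractions = sb.expected_occupancy_fractions(bead_fit, kmax=3)
print("expected droplet fractions k=0..3 (+tail):",
      [round(float(f), 4) for f in fractions])

pe = sb.pairing_efficiency(semibulk_fit.lambda_hat, bead_fit.lambda_hat)
print(f"pairing efficiency ~ lambda_s * lambda_b = {pe.rounded(2)}")
print(f"exact single-bead-single-semibulk probability = {pe.exact_single_single:.5f}")
# The product approximation says ~2% of droplets are usable; the exact
# one-of-each probability is lower because each Poisson(λ) also spends
# mass on empty and multiply-loaded droplets.
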