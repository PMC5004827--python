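"""Date species splits from between-group divergence: T = d_xy / (2 mu).

d_xy is the mean between-group K2P distance; its standard error comes
from a bootstrap over alignment columns, and the +/-2SE interval is
propagated through a slow/mean/fast substitution-rate triple to give a
conservative age interval (wide bound paired with the opposite rate
extreme).
"""

from matriline import (
    RateCalibration,
    date_divergence,
    group_divergence,
    make_fixture,
)

alignment, metadata, truth = make_fixture("six_species_radiation")
by = metadata.by_species()
rates = RateCalibration()  # 2.02e-8 / 3.68e-8 / 5.34e-8 per site per year

print("pair                      d_xy      t_mid      [t_low - t_high]   true split")
for a, b in [("culpaeus", "griseus"), ("fulvipes", "gymnocercus"),
             ("vetulus", "sechurae")]:
    div = group_divergence(alignment, by[a], by[b], n_bootstrap=1000, seed=0,
                           label=f"{a} X {b}")
    age = date_divergence(div, rates)
    print(
        f"{div.label:<24} {div.d_xy:.4f} {age.t_mid:>10,.0f}  "
        f"[{age.t_low:,.0f} - {age.t_high:,.0f}]  {truth.split_time(a, b):,.0f}"
    )

print("\nt_mid uses the mean rate; the interval spans the d_xy +/- 2SE bounds")
print("evaluated at the fast and slow rates, so it is deliberately wide.")
print("a single 588-bp realization carries ~20% stochastic error on d_xy,")
print("so point estimates scatter around the true splits within the interval.")
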