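"""Compute the daily stress index for a generated severe-deficit season
and classify the environment.

The SID adds a soil-water-deficit utilisation percentage (deficit /
easily-accessible reserve x 100) to a small heat bonus from hours above
30 degC; daily values are summed over the flowering fortnight (Pflo,
Jul 1-15) and the culture window (Ptot, May 16 - Aug 15) and averaged
per half-month to rank environments.
"""

from maizedig import simulate, weather

w = simulate.gen_weather("severe_deficit", seed=1)
series = weather.sid_series(w, eawr=100.0, env="WD-like")

pflo = weather.period_sum(series, weather.PFLO)
ptot = weather.period_sum(series, weather.PTOT)
profile = weather.halfmonth_means(series)
category = weather.classify_environment(profile)
summary = weather.env_summary(w, weather.PTOT)

print(f"Pflo SID sum : {pflo:8.1f}   (15-day flowering window)")
print(f"Ptot SID sum : {ptot:8.1f}   (92-day culture window)")
print(f"TWI          : {summary.twi:8.1f} mm rain+irrigation over Ptot")
print(f"HSD          : {summary.hsd:8.0f} h above 30 degC over Ptot")
print("\nHalf-month mean SID profile:")
for r in profile.itertuples():
    flag = "" if r.complete else " (partial)"
    print(f"  {r.start} .. {r.end}: {r.mean_sid:7.1f}{flag}")
print(f"\nCategory: {category.label} (Pflo mean {category.pflo_mean:.1f})")
print("A mean above 100 means the easily accessible reserve is exhausted;")
print("above 180 over flowering the season counts as severe stress.")
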