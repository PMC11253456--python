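"""Measure catastrophic health expenditure for a single household.

Annual health spending is direct medical + direct non-medical + indirect
costs (lost days valued at a daily rate, the human-capital approach); the
household is catastrophic when the health share of its total budget
strictly exceeds the threshold.
"""

from chegap import ExpenditureProfile, annual_health_expenditure, che_flag

profile = ExpenditureProfile(
    food=42000.0,              # currency/year
    nonfood_nonhealth=18000.0,
    direct_medical=5200.0,
    direct_nonmedical=900.0,   # transport, cafeteria, lodging
    lost_days=14.0,            # patient + caregiver days
    daily_valuation=150.0,     # currency/day
)

health = annual_health_expenditure(profile)
print(f"annual health expenditure : {health:,.0f}")

for threshold in (0.10, 0.25, 0.40):
    result = che_flag(profile, threshold=threshold)
    print(f"threshold {threshold:.2f}: share = {result.share:.3f} "
          f"-> catastrophic = {result.catastrophic}")
# The share (health / total budget, health included in the total) is fixed;
# raising the threshold can only switch households out of the flag.
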