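"""Generate a synthetic supplier/recipient arrival stream and inspect it.

The default design emits 3,000 recipient requests and 1,800 supplier lots
over a 120-unit horizon, with supplier quantities calibrated so total
demand is about 0.8 of total supply.
"""

from collections import Counter

from epimatch import StreamConfig, generate_stream, realized_ratio

config = StreamConfig(seed=42)
recipients, suppliers = generate_stream(config)

print(f"recipients: {len(recipients)}, suppliers: {len(suppliers)}")
print(f"realized demand/supply quantity ratio: {realized_ratio(recipients, suppliers):.4f}")
print(f"priority mix: {Counter(r.dr for r in recipients)}")
print(f"supply tiers: {Counter(s.sr for s in suppliers)}")
print(f"first arrival: t={min(r.request_time for r in recipients)}, "
      f"last: t={max(r.request_time for r in recipients)}")

# The ratio sits within 2% of the 0.8 target for any seed; priorities are a
# fair coin and tiers are uniform, so roughly half the recipients are
# high-priority and each supply tier holds about a third of the lots.
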