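"""Estimate displacement for AIS-style records that report only DWT.

Each vessel type has its own conversion strategy: a published DWT
regression (bulk carrier, container ship, tanker, tug), the reciprocal of a
class deadweight coefficient C_D = DWT/mass (cruise, ferry, fishing,
passenger, pleasure craft, sailing), or the mean of three estimates for the
heterogeneous categories.
"""

import vesselmass as vm

records = [
    vm.VesselRecord(record_id="a", vessel_type="cruise", loa_m=219.1, dwt_tonnes=6059),
    vm.VesselRecord(record_id="b", vessel_type="tug", loa_m=44.1, dwt_tonnes=952),
    vm.VesselRecord(record_id="c", vessel_type="tanker", loa_m=198.4, dwt_tonnes=63904),
    vm.VesselRecord(record_id="d", vessel_type="government_research", loa_m=68.1,
                    dwt_tonnes=1617),
    # catalogue-style record: net weight + berths instead of DWT
    vm.VesselRecord(record_id="e", vessel_type="sailing", loa_m=12.0,
                    net_weight_kg=4000, capacity_persons=6),
]

masses, methods = vm.estimate_fleet(records)
print(f"{'id':<4}{'type':<22}{'method':<16}{'displacement (kg)':>18}")
for r, m, meth in zip(records, masses, methods):
    print(f"{r.record_id:<4}{r.vessel_type.value:<22}{meth:<16}{m:>18,.0f}")

print(
    "\n'dwt_ratio' divides DWT by the class deadweight coefficient;"
    "\n'dwt_mixed_mean' averages three kg-converted estimates;"
    "\n'net_weight' adds 95 kg (person + luggage) per berth."
)
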