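# Deadweight-tonnage -> displacement conversion strategies, by vessel type.
# version 1. Naval-architecture sources express some equations in U.S.
# customary tons (1016 kg); output_unit records the dialect of each equation's
# result. Ratio strategies are the reciprocal of a deadweight coefficient
# C_D = DWT / displacement fixed at the sample-average LOA (anchor_loa_m);
# cd_spec names the (LOA, C_D) endpoint range the coefficient was
# interpolated from.
version: "1"
cd_specs:
  large_passenger:
    {loa_lo_m: 200.0, cd_lo: 0.23, loa_hi_m: 360.0, cd_hi: 0.34}
  ropax:
    {loa_lo_m: 85.0, cd_lo: 0.16, loa_hi_m: 120.0, cd_hi: 0.33}
  stern_trawler:
    {loa_lo_m: 44.0, cd_lo: 0.30, loa_hi_m: 82.0, cd_hi: 0.58}
  small_passenger:
    {loa_lo_m: 50.0, cd_lo: 0.15, loa_hi_m: 120.0, cd_hi: 0.25}
strategies:
  bulk_carrier:
    form: power
    scale: 2.21442
    exponent: 0.943855
    output_unit: us_tons
    source_label: "bulk-carrier DWT regression"
  container_ship:
    form: power
    scale: 1.77955
    exponent: 0.975578
    output_unit: us_tons
    source_label: "container-ship DWT regression"
  cruise:
    form: ratio
    scale: 4.1152
    output_unit: tonnes
    cd: 0.243
    cd_spec: large_passenger
    anchor_loa_m: 219.1
    source_label: "large-passenger deadweight coefficient"
  ferry:
    form: ratio
    scale: 4.2918
    output_unit: tonnes
    cd: 0.233
    cd_spec: ropax
    anchor_loa_m: 100.1
    source_label: "ferry / Ro-Ro / Ro-Pax deadweight coefficient"
  fishing:
    form: ratio
    scale: 2.9940
    output_unit: tonnes
    cd: 0.334
    cd_spec: stern_trawler
    anchor_loa_m: 48.6
    source_label: "stern-trawler deadweight coefficient"
  government_research:
    form: mixed
    anchor_loa_m: 68.1
    source_label: "mean of container-ship, fishing and small-passenger estimates"
    components:
      - form: power
        scale: 1.77955
        exponent: 0.975578
        output_unit: us_tons
        source_label: "container-ship DWT regression"
      - form: ratio
        cd: 0.478
        output_unit: tonnes
        cd_spec: stern_trawler
        source_label: "stern-trawler deadweight coefficient at 68.1 m"
      - form: ratio
        cd: 0.176
        output_unit: tonnes
        cd_spec: small_passenger
        source_label: "small-passenger deadweight coefficient at 68.1 m"
  other:
    form: mixed
    anchor_loa_m: 93.4
    source_label: "mean of container-ship, fishing and small-passenger estimates"
    components:
      - form: power
        scale: 1.77955
        exponent: 0.975578
        output_unit: us_tons
        source_label: "container-ship DWT regression"
      - form: ratio
        cd: 0.580
        output_unit: tonnes
        cd_spec: stern_trawler
        source_label: "stern-trawler deadweight coefficient at 93.4 m (clamped)"
      - form: ratio
        cd: 0.212
        output_unit: tonnes
        cd_spec: small_passenger
        source_label: "small-passenger deadweight coefficient at 93.4 m"
  passenger:
    form: ratio
    scale: 5.988
    output_unit: tonnes
    cd: 0.167
    cd_spec: small_passenger
    anchor_loa_m: 62.2
    source_label: "small-passenger deadweight coefficient"
  pleasure_craft:
    form: ratio
    scale: 6.2893
    output_unit: tonnes
    cd: 0.159
    cd_spec: small_passenger
    anchor_loa_m: 56.3
    source_label: "small-passenger deadweight coefficient"
  sailing:
    form: ratio
    scale: 6.4516
    output_unit: tonnes
    cd: 0.155
    cd_spec: small_passenger
    anchor_loa_m: 53.2
    source_label: "small-passenger deadweight coefficient"
  tanker:
    form: linear
    scale: 1.1213
    offset: 4773.95
    output_unit: us_tons
    source_label: "tanker DWT regression"
  tug:
    form: power
    scale: 5.2301
    exponent: 0.8752
    output_unit: tonnes
    source_label: "offshore tug / supply vessel DWT regression"
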