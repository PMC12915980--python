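# Default synthetic-fleet composition, v1: per-type sample sizes split by
# source (AIS static data vs online catalogues) and the LOA summary
# statistics (metres) that parameterise the truncated-normal length draws.
# Totals 873 records across twelve types.
version: "1"
types:
  bulk_carrier:
    {n_ais: 100, n_online: 0, loa_min_m: 85.9, loa_max_m: 300.0, loa_mean_m: 221.0, loa_sd_m: 50.1}
  container_ship:
    {n_ais: 100, n_online: 0, loa_min_m: 84.0, loa_max_m: 336.6, loa_mean_m: 240.7, loa_sd_m: 61.1}
  cruise:
    {n_ais: 92, n_online: 0, loa_min_m: 90.6, loa_max_m: 344.3, loa_mean_m: 219.1, loa_sd_m: 69.7}
  ferry:
    {n_ais: 47, n_online: 0, loa_min_m: 25.5, loa_max_m: 203.3, loa_mean_m: 100.1, loa_sd_m: 45.0}
  fishing:
    {n_ais: 39, n_online: 61, loa_min_m: 4.6, loa_max_m: 104.5, loa_mean_m: 25.9, loa_sd_m: 22.2}
  government_research:
    {n_ais: 48, n_online: 4, loa_min_m: 7.5, loa_max_m: 182.5, loa_mean_m: 63.7, loa_sd_m: 31.1}
  other:
    {n_ais: 43, n_online: 6, loa_min_m: 6.2, loa_max_m: 178.8, loa_mean_m: 83.3, loa_sd_m: 45.3}
  passenger:
    {n_ais: 4, n_online: 26, loa_min_m: 6.2, loa_max_m: 95.1, loa_mean_m: 23.2, loa_sd_m: 20.9}
  pleasure_craft:
    {n_ais: 42, n_online: 20, loa_min_m: 4.9, loa_max_m: 81.2, loa_mean_m: 42.2, loa_sd_m: 23.0}
  sailing:
    {n_ais: 7, n_online: 32, loa_min_m: 4.6, loa_max_m: 76.0, loa_mean_m: 20.3, loa_sd_m: 18.2}
  tanker:
    {n_ais: 100, n_online: 0, loa_min_m: 110.0, loa_max_m: 277.0, loa_mean_m: 198.4, loa_sd_m: 44.2}
  tug:
    {n_ais: 102, n_online: 0, loa_min_m: 25.2, loa_max_m: 95.0, loa_mean_m: 44.1, loa_sd_m: 18.6}
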