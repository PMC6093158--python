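{
  "description": "Published bookkeeping of the 1978/2003 Japanese national sika deer surveys and of the scenario projections, used as fixed inputs for worked-example checks. Areas in 1e3 km^2; the suitability-change contingency table cross-classifies cells by sign of the 1978->2003 suitability change (columns: increased, decreased) and by whether the land-use or the climate block dominates in absolute value (rows: |LU|>|CL|, |LU|<|CL|).",
  "n_cells": 15256,
  "total_area_1e3_km2": 351.8,
  "occupancy": {
    "present_1978": 4079,
    "absent_1978": 11177,
    "persisted": 3800,
    "lost": 279,
    "colonized": 3333,
    "present_2003": 7133,
    "absent_2003": 8123,
    "never_occupied": 7844
  },
  "suitability_change": {
    "n_increased": 10925,
    "n_decreased": 4331,
    "contingency": [[220, 4011], [10705, 320]]
  },
  "projection_2103_areas_1e3_km2": {
    "baseline": 304.2,
    "lu_only": [308.5, 312.1],
    "cl_only": [313.7, 334.0],
    "lucl": [318.3, 340.4]
  }
}
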