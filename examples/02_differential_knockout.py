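"""Differential CHD4 occupancy upon Gfi1 knockout.

Starting from 1128 planted GFI1/CHD4 co-occupied sites, a knockout CHD4
peak set is constructed that retains CHD4 at 287 of them and adds 9
novel peaks. The differential caller labels each wild-type co-occupied
site lost or retained and flags knockout-specific sites as gained.
"""

import cooccupy as cc

cfg = cc.SyntheticConfig(seed=1)
genome = cc.make_genome(cfg)
gfi1, chd4_wt, truth, free = cc.plant_peaks(cfg, genome)
chd4_ko, truth = cc.plant_ko(cfg, chd4_wt, truth, free, genome)

shared = cc.IntervalSet(
    [iv for iv in gfi1 if truth.site_class[iv.name] == "shared"], merged=True)
calls, counts = cc.differential(shared, chd4_wt, chd4_ko)

print(f"co-occupied sites in WT : {len(shared)}")
print(f"lost CHD4 in knockout   : {counts['lost']}")
print(f"retained CHD4           : {counts['retained']}")
print(f"gained (KO-specific)    : {counts['gained']}")

# lost + retained partition the co-occupied sites; gained sites overlap
# no wild-type CHD4 peak at all.
assert counts["lost"] + counts["retained"] == len(shared)
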