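# SYNTHETIC reference table for an 18-color + 6-white-balance paper color
# target layout (4 rows x 6 columns; the last row holds the white-balance
# squares).  The vendor does not publish CIELAB values for the low-cost
# target, so this stand-in reuses the 18 chromatic patches of the classic
# chart plus a 6-step neutral ramp.  Replace with measured values for
# quantitative work against a physical target.
patch_id,role,L,a,b
dark_skin,color,37.986,13.555,14.059
light_skin,color,65.711,18.130,17.810
blue_sky,color,49.927,-4.880,-21.925
foliage,color,43.139,-13.095,21.905
blue_flower,color,55.112,8.844,-25.399
bluish_green,color,70.719,-33.397,-0.199
orange,color,62.661,36.067,57.096
purplish_blue,color,40.020,10.410,-45.964
moderate_red,color,51.124,48.239,16.248
purple,color,30.325,22.976,-21.587
yellow_green,color,72.532,-23.709,57.255
orange_yellow,color,71.941,19.363,67.857
blue,color,28.778,14.179,-50.297
green,color,55.261,-38.342,31.370
red,color,42.101,53.378,28.190
yellow,color,81.733,4.039,79.819
magenta,color,51.935,49.986,-14.574
cyan,color,51.038,-28.631,-28.638
wb_100,white_balance,95.000,0.000,0.000
wb_80,white_balance,80.000,0.000,0.000
wb_65,white_balance,65.000,0.000,0.000
wb_50,white_balance,50.000,0.000,0.000
wb_35,white_balance,35.000,0.000,0.000
wb_20,white_balance,20.000,0.000,0.000
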