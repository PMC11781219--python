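# CIELAB reference values for the classic 24-patch color rendition chart,
# as widely published for the pre-2014 production run (D50-referenced
# averages; treated here as the chart's nominal values).  The bottom
# neutral row serves as white-balance patches and is excluded from the
# color-error mean.  Edit or replace to match your own target's datasheet.
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
white_95,white_balance,96.539,-0.425,1.186
neutral_8,white_balance,81.257,-0.638,-0.335
neutral_65,white_balance,66.766,-0.734,-0.504
neutral_5,white_balance,50.867,-0.153,-0.270
neutral_35,white_balance,35.656,-0.421,-1.231
black_2,white_balance,20.461,-0.079,-0.973
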