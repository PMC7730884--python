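activity,joint,population,impulse
walking,hip,Controls,192.77
walking,hip,HipOA,175.74
walking,hip,KneeOA,183.14
walking,knee,Controls,140.83
walking,knee,HipOA,132.36
walking,knee,KneeOA,140.92
ascending_stairs,hip,Controls,213.34
ascending_stairs,hip,HipOA,233.28
ascending_stairs,hip,KneeOA,274.51
ascending_stairs,knee,Controls,229.20
ascending_stairs,knee,HipOA,235.43
ascending_stairs,knee,KneeOA,242.27
descending_stairs,hip,Controls,215.26
descending_stairs,hip,HipOA,223.51
descending_stairs,hip,KneeOA,290.58
descending_stairs,knee,Controls,218.18
descending_stairs,knee,HipOA,225.02
descending_stairs,knee,KneeOA,240.63
sit_down,hip,Controls,136.34
sit_down,hip,HipOA,133.68
sit_down,hip,KneeOA,154.51
sit_down,knee,Controls,248.87
sit_down,knee,HipOA,240.45
sit_down,knee,KneeOA,234.37
stand_up,hip,Controls,124.95
stand_up,hip,HipOA,111.03
stand_up,hip,KneeOA,129.74
stand_up,knee,Controls,221.54
stand_up,knee,HipOA,199.70
stand_up,knee,KneeOA,199.74
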