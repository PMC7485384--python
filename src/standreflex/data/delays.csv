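muscle,delay_ms
iliopsoas,40
gluteals,40
rectus_femoris,82
biceps_femoris_lh,60
biceps_femoris_sh,60
vastus,100
gastrocnemius,54
soleus,44
tibialis_anterior,35
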