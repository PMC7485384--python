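name,u0,g_ffb,g_lfb,l_off,value
iliopsoas,0.5010135018922407,0.0,-0.5885795915021291,1.002659188215071,
gluteals,0.3040267752880045,0.0,1.1101029064976466,0.6014590205649523,
rectus_femoris,0.462590627616845,0.0,-1.1182719727889676,0.8628739417618522,
biceps_femoris_lh,0.28749524378576485,0.0,-1.614089910158065,0.5319878413195772,
biceps_femoris_sh,0.022838463760305554,0.0,2.0896724509307187,0.7546970303168518,
vastus,0.2275071142453913,0.0,-1.276617221342671,0.4753012319282395,
gastrocnemius,0.4868263883631172,0.0,1.8758083116048423,0.6240648537587936,
soleus,0.690943582896184,0.0,2.7919605835799612,0.8875844543549631,
tibialis_anterior,0.5000821592404036,0.0,-2.818126295199209,0.30074667641821573,
x_heel,,,,,0.09503604001224973
x_toe,,,,,0.09765685950877162
z_heel,,,,,0.14623650481423245
z_toe,,,,,0.3139019465355119
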