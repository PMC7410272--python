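model_variant,level,modality,activity,mean,sd
intact,0.25,bending,jumping_jack,33.1,13.3
intact,0.25,torsion,internal_rotation,19.8,11.7
intact,0.25,axial,jumping_jack,123.8,29.4
body_powered,0.25,bending,jumping_jack,22.9,2.6
body_powered,0.25,torsion,jug_lift,4.3,1.8
body_powered,0.25,axial,briefcase_carry,78.2,6.3
myoelectric_hook,0.25,bending,jug_lift,25.6,2.9
myoelectric_hook,0.25,torsion,internal_rotation,10.0,4.7
myoelectric_hook,0.25,axial,briefcase_carry,89.9,6.7
myoelectric_hand,0.25,bending,jumping_jack,29.8,8.5
myoelectric_hand,0.25,torsion,internal_rotation,15.9,7.4
myoelectric_hand,0.25,axial,briefcase_carry,94.5,7.0
advanced,0.25,bending,jumping_jack,58.8,16.8
advanced,0.25,torsion,internal_rotation,31.8,14.7
advanced,0.25,axial,jumping_jack,161.9,21.7
intact,0.50,bending,jumping_jack,26.3,10.3
intact,0.50,torsion,internal_rotation,19.8,11.7
intact,0.50,axial,jumping_jack,106.1,26.1
body_powered,0.50,bending,jug_lift,20.1,2.3
body_powered,0.50,torsion,jug_lift,4.3,1.8
body_powered,0.50,axial,briefcase_carry,77.8,6.3
myoelectric_hook,0.50,bending,jug_lift,22.3,2.5
myoelectric_hook,0.50,torsion,internal_rotation,10.0,4.7
myoelectric_hook,0.50,axial,briefcase_carry,89.5,6.7
myoelectric_hand,0.50,bending,jumping_jack,24.4,6.8
myoelectric_hand,0.50,torsion,internal_rotation,15.9,7.4
myoelectric_hand,0.50,axial,briefcase_carry,94.1,7.0
advanced,0.50,bending,jumping_jack,48.4,13.7
advanced,0.50,torsion,internal_rotation,31.8,14.7
advanced,0.50,axial,jumping_jack,160.9,21.8
intact,0.75,bending,jumping_jack,20.7,7.8
intact,0.75,torsion,internal_rotation,19.8,11.7
intact,0.75,axial,briefcase_carry,92.8,10.5
body_powered,0.75,bending,jug_lift,17.4,2.0
body_powered,0.75,torsion,jug_lift,4.3,1.8
body_powered,0.75,axial,briefcase_carry,75.8,6.1
myoelectric_hook,0.75,bending,jug_lift,19.1,2.2
myoelectric_hook,0.75,torsion,internal_rotation,10.0,4.7
myoelectric_hook,0.75,axial,briefcase_carry,87.5,6.6
myoelectric_hand,0.75,bending,jug_lift,20.1,2.3
myoelectric_hand,0.75,torsion,internal_rotation,15.9,7.4
myoelectric_hand,0.75,axial,briefcase_carry,92.1,6.9
advanced,0.75,bending,jumping_jack,38.9,10.7
advanced,0.75,torsion,internal_rotation,31.8,14.7
advanced,0.75,axial,jumping_jack,155.4,21.2
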