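tissue,type,measured,units,ref_low,ref_high
Adrenal glands (combined),weight,6.46,g,6.2,6.7
Brain,weight,1052,g,1064,1064
Brain CSF,volume,108.7,cm3,110,120
Heart,weight,56.7,g,56,56
Liver,volume,335,cm3,299.7,426.2
Liver,length,82.3,mm,85,85
Spleen,weight,38.5,g,37,37
Spleen,length,70,mm,70,70
Right Kidney,weight,48.6,g,47,47
Right Kidney,length,65.8,mm,61,61
Left Kidney,weight,48,g,46,46
Left Kidney,length,68.8,mm,66,66
Thymus,weight,19.8,g,20,38
Testes (combined),weight,2.9,g,2.3,4.3
Sternal Bone,length,10.2,cm,8,12.5
Radius/Humerus,ratio,0.78,,0.75,0.75
Tibia/Femur,ratio,0.81,,0.81,0.81
Humerus/Femur,ratio,0.71,,0.71,0.71
Radius/Tibia,ratio,0.69,,0.65,0.65
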