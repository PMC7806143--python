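tissue,f_MHz,sigma_S_per_m,eps_r,ratio_sigma,ratio_eps,density_kg_m3,T1_ms,T2_ms,PD
Adrenal Gland,64,0.629286,64.9826,1.4,1.15,1028,nan,nan,nan
Adrenal Gland,128,0.639714,63.7913,1.4,1.15,1028,nan,nan,nan
Air,64,0,1,1.0,1.0,1.2,nan,nan,0.0
Air,128,0,1,1.0,1.0,1.2,nan,nan,0.0
Bile,64,1.4818,105.44,1.0,1.0,928,nan,nan,nan
Bile,128,1.5764,88.9,1.0,1.0,928,nan,nan,nan
Blood,64,1.2067,86.44,1.0,1.0,1050,1932,275,0.9
Blood,128,1.2486,73.16,1.0,1.0,1050,1932,275,0.9
Blood Vessel Wall,64,0.429286,68.6393,1.4,1.22,1102,nan,nan,nan
Blood Vessel Wall,128,0.478929,55.9918,1.4,1.22,1102,nan,nan,nan
Bone (Cortical),64,0.0595417,16.6834,2.4,1.99,1908,250,1.0,0.1
Bone (Cortical),128,0.0673333,14.7186,2.4,1.99,1908,250,1.0,0.1
Bone Marrow (Red),64,0.154357,16.4344,1.4,1.22,1029,nan,nan,nan
Bone Marrow (Red),128,0.162,13.541,1.4,1.22,1029,nan,nan,nan
Brain (Grey Matter),64,0.510875,97.4286,1.6,1.33,1045,1820,99,0.85
Brain (Grey Matter),128,0.58675,73.5188,1.6,1.33,1045,1820,99,0.85
Brain (White Matter),64,0.2915,67.8346,1.6,1.33,1041,1084,69,0.7
Brain (White Matter),128,0.342125,52.5338,1.6,1.33,1041,1084,69,0.7
Cartilage,64,0.452071,62.918,1.4,1.22,1100,nan,nan,nan
Cartilage,128,0.488357,52.9262,1.4,1.22,1100,nan,nan,nan
Cerebellum,64,0.719,116.353,1.6,1.33,1045,1820,99,0.85
Cerebellum,128,0.829375,79.7368,1.6,1.33,1045,1820,99,0.85
Cerebrospinal Fluid,64,2.066,97.31,1.0,1.0,1007,4163,1500,1.0
Cerebrospinal Fluid,128,2.143,84.04,1.0,1.0,1007,4163,1500,1.0
Connective Tissue,64,0.474357,59.4918,1.4,1.22,1027,nan,nan,nan
Connective Tissue,128,0.498714,51.8607,1.4,1.22,1027,nan,nan,nan
Dura,64,0.706688,73.2632,1.6,1.33,1174,nan,nan,nan
Dura,128,0.751688,55.9699,1.6,1.33,1174,nan,nan,nan
Eye (Cornea),64,1.00057,87.377,1.4,1.22,1051,nan,nan,nan
Eye (Cornea),128,1.05871,71.459,1.4,1.22,1051,nan,nan,nan
Eye (Lens),64,0.285857,50.3361,1.4,1.22,1076,nan,nan,nan
Eye (Lens),128,0.312714,42.7951,1.4,1.22,1076,nan,nan,nan
Eye (Retina),64,0.510875,97.4286,1.6,1.33,1039,nan,nan,nan
Eye (Retina),128,0.58675,73.5188,1.6,1.33,1039,nan,nan,nan
Eye (Sclera),64,0.882643,75.3033,1.4,1.22,1032,nan,nan,nan
Eye (Sclera),128,0.917643,65,1.4,1.22,1032,nan,nan,nan
Eye (Vitreous Humor),64,1.50314,69.123,1.4,1.22,1005,nan,nan,nan
Eye (Vitreous Humor),128,1.50536,69.0656,1.4,1.22,1005,nan,nan,nan
Fat,64,0.0661429,13.6475,1.4,1.22,911,371,133,0.9
Fat,128,0.0697143,12.3689,1.4,1.22,911,371,133,0.9
Gallbladder,64,0.966,87.4,1.0,1.0,1071,nan,nan,nan
Gallbladder,128,1.0418,74.14,1.0,1.0,1071,nan,nan,nan
Heart Muscle,64,0.678429,106.517,1.4,1.18,1081,1471,47,0.8
Heart Muscle,128,0.766143,84.2542,1.4,1.18,1081,1471,47,0.8
Intervertebral Disc,64,0.843357,51.459,1.4,1.22,1100,nan,nan,nan
Intervertebral Disc,128,0.860214,49.6967,1.4,1.22,1100,nan,nan,nan
Kidney,64,0.741286,118.557,1.4,1.22,1066,nan,nan,nan
Kidney,128,0.852286,89.6148,1.4,1.22,1066,nan,nan,nan
Large Intestine,64,0.638143,94.6639,1.4,1.22,1088,nan,nan,nan
Large Intestine,128,0.705214,76.5738,1.4,1.22,1088,nan,nan,nan
Liver,64,0.448,80.5574,1.2,1.22,1079,nan,nan,nan
Liver,128,0.510917,64.2541,1.2,1.22,1079,nan,nan,nan
Lung,64,0.289,37.0984,1.4,1.22,394,1270,30,0.2
Lung,128,0.315643,29.4672,1.4,1.22,394,1270,30,0.2
Muscle,64,0.688214,72.2373,1.4,1.18,1090,1412,50,0.8
Muscle,128,0.719214,63.4915,1.4,1.18,1090,1412,50,0.8
Nerve,64,0.312143,55.0656,1.4,1.22,1075,nan,nan,nan
Nerve,128,0.353786,44.0656,1.4,1.22,1075,nan,nan,nan
Salivary Gland,64,0.679071,80.6174,1.4,1.15,1048,nan,nan,nan
Salivary Gland,128,0.688857,79.4609,1.4,1.15,1048,nan,nan,nan
Skin,64,0.435733,92.1705,1.5,1.29,1109,1400,40,0.65
Skin,128,0.522733,65.4341,1.5,1.29,1109,1400,40,0.65
Small Intestine,64,1.59143,118.361,1.4,1.22,1030,nan,nan,nan
Small Intestine,128,1.69286,87.9754,1.4,1.22,1030,nan,nan,nan
Spleen,64,0.743929,110.557,1.4,1.22,1089,nan,nan,nan
Spleen,128,0.835214,82.8934,1.4,1.22,1089,nan,nan,nan
Stomach,64,0.877857,85.8197,1.4,1.22,1088,nan,nan,nan
Stomach,128,0.912786,74.8934,1.4,1.22,1088,nan,nan,nan
Tendon/Ligament,64,0.474357,59.4918,1.4,1.22,1142,nan,nan,nan
Tendon/Ligament,128,0.498714,51.8607,1.4,1.22,1142,nan,nan,nan
Testis,64,0.884857,84.5246,1.4,1.22,1082,nan,nan,nan
Testis,128,0.926429,72.1311,1.4,1.22,1082,nan,nan,nan
Thymus,64,0.637429,55.8115,1.4,1.22,1023,nan,nan,nan
Thymus,128,0.645143,54.877,1.4,1.22,1023,nan,nan,nan
Thyroid Gland,64,0.778286,73.9478,1.4,1.15,1050,nan,nan,nan
Thyroid Gland,128,0.804143,66.7826,1.4,1.15,1050,nan,nan,nan
Tongue,64,0.652143,75.3033,1.4,1.22,1090,nan,nan,nan
Tongue,128,0.687143,65,1.4,1.22,1090,nan,nan,nan
Trachea,64,0.528429,58.8934,1.4,1.22,1080,nan,nan,nan
Trachea,128,0.559357,50.5738,1.4,1.22,1080,nan,nan,nan
Ureter/Urethra,64,0.429286,68.6393,1.4,1.22,1102,nan,nan,nan
Ureter/Urethra,128,0.478929,55.9918,1.4,1.22,1102,nan,nan,nan
Urinary Bladder Wall,64,0.287357,24.5984,1.4,1.22,1086,nan,nan,nan
Urinary Bladder Wall,128,0.298,21.8607,1.4,1.22,1086,nan,nan,nan
Urine,64,1.75,49.95,1.0,1.0,1024,nan,nan,nan
Urine,128,1.75,49.95,1.0,1.0,1024,nan,nan,nan
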