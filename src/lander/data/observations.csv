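deployment_id,taxon,n_max,t_arr_min,pct_images,provenance
1,Hexanchus griseus,1,116,6.2,inferred: single-entry row; upper-slope shark placed at the shallowest deployment
1,Centrophorus granulosus,1,99,3.1,table-order: the three cells (counts 1-3) read left to right across the shallow deployments 1-3
2,Centrophorus granulosus,2,28,31.5,table-order
3,Centrophorus granulosus,3,14,25.0,table-order
3,Dipturus oxyrinchus,1,49,1.9,inferred: single-entry row; slope skate placed at 943 m
1,Conger conger,1,4,6.5,inferred: single-entry row; shelf-edge necrophage placed at the shallowest deployment
1,Helicolenus dactylopterus,1,23,27.5,inferred: two cells among deployments 1-3 read left to right
2,Helicolenus dactylopterus,1,91,4.6,inferred
1,Polyprion americanus,2,63,34.4,inferred: single-entry row; 450-650 m species placed at the shallowest deployment
1,Plesionika heterocarpus,4,1,28.7,inferred: single-entry row; shelf/upper-slope shrimp placed at the shallowest deployment
2,Aristeus antennatus,3,31,7.2,inferred: two cells among deployments 1-3; read left to right from deployment 2
3,Aristeus antennatus,2,19,10.2,inferred
4,Nettastoma melanurum,3,58,19.8,inferred: combined-data faunal group at 1208-1346 m places the species at 1346 m
4,Lepidion lepidion,1,55,2.1,inferred: species dominant 1000-1400 m; two cells read left to right from deployment 4
5,Lepidion lepidion,2,76,8.4,inferred
5,Etmopterus spinax,2,4,9.4,inferred: reported regional range 1500-2300 m and no elasmobranch beyond deployment 5
5,Chaceon mediterraneus,1,156,12.6,inferred: bathyal crab; must lie in 1000-2000 m to preserve the stated species-overlap pattern
4,Acanthephyra eximia,7,12,59.5,results-text: present in every deployment deeper than 1000 m; cells read left to right
5,Acanthephyra eximia,14,2,89.0,results-text
6,Acanthephyra eximia,2,6,13.0,results-text
7,Acanthephyra eximia,29,3,99.4,results-text: N_max 29 and 99.4% of images at 4204 m
8,Acanthephyra eximia,8,1,22.1,results-text: immediately present on landing at 5111 m
6,Coryphaenoides mediterraneus,7,8,79.6,results-text: the only fish at the three deepest deployments
7,Coryphaenoides mediterraneus,8,67,84.9,results-text
8,Coryphaenoides mediterraneus,1,174,0.4,results-text: first arrival after 2.9 h at 5111 m
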