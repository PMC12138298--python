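display	system	code	synonyms
spleen	sct	78961009	
right kidney	local	kidney_right	kidney_right
left kidney	local	kidney_left	kidney_left
gallbladder	sct	28231008	
liver	sct	10200004	
stomach	sct	69695003	
aorta	sct	15825003	
inferior vena cava	local	inferior_vena_cava	inferior_vena_cava
portal vein and splenic vein	local	portal_vein_and_splenic_vein	portal_vein_and_splenic_vein
pancreas	sct	15776009	
right adrenal gland	local	adrenal_gland_right	adrenal_gland_right
left adrenal gland	local	adrenal_gland_left	adrenal_gland_left
left lung upper lobe	local	lung_upper_lobe_left	lung_upper_lobe_left
left lung lower lobe	local	lung_lower_lobe_left	lung_lower_lobe_left
right lung upper lobe	local	lung_upper_lobe_right	lung_upper_lobe_right
right lung middle lobe	local	lung_middle_lobe_right	lung_middle_lobe_right
right lung lower lobe	local	lung_lower_lobe_right	lung_lower_lobe_right
L5 vertebra	local	vertebrae_L5	vertebrae_L5
L4 vertebra	local	vertebrae_L4	vertebrae_L4
L3 vertebra	local	vertebrae_L3	vertebrae_L3
L2 vertebra	local	vertebrae_L2	vertebrae_L2
L1 vertebra	local	vertebrae_L1	vertebrae_L1
T12 vertebra	local	vertebrae_T12	vertebrae_T12
T11 vertebra	local	vertebrae_T11	vertebrae_T11
T10 vertebra	local	vertebrae_T10	vertebrae_T10
T9 vertebra	local	vertebrae_T9	vertebrae_T9
T8 vertebra	local	vertebrae_T8	vertebrae_T8
T7 vertebra	local	vertebrae_T7	vertebrae_T7
T6 vertebra	local	vertebrae_T6	vertebrae_T6
T5 vertebra	local	vertebrae_T5	vertebrae_T5
T4 vertebra	local	vertebrae_T4	vertebrae_T4
T3 vertebra	local	vertebrae_T3	vertebrae_T3
T2 vertebra	local	vertebrae_T2	vertebrae_T2
T1 vertebra	local	vertebrae_T1	vertebrae_T1
C7 vertebra	local	vertebrae_C7	vertebrae_C7
C6 vertebra	local	vertebrae_C6	vertebrae_C6
C5 vertebra	local	vertebrae_C5	vertebrae_C5
C4 vertebra	local	vertebrae_C4	vertebrae_C4
C3 vertebra	local	vertebrae_C3	vertebrae_C3
C2 vertebra	local	vertebrae_C2	vertebrae_C2
C1 vertebra	local	vertebrae_C1	vertebrae_C1
esophagus	sct	32849002	
trachea	sct	44567001	
heart myocardium	local	heart_myocardium	heart_myocardium
left heart atrium	local	heart_atrium_left	heart_atrium_left
left heart ventricle	local	heart_ventricle_left	heart_ventricle_left
right heart atrium	local	heart_atrium_right	heart_atrium_right
right heart ventricle	local	heart_ventricle_right	heart_ventricle_right
pulmonary artery	local	pulmonary_artery	pulmonary_artery
brain	sct	12738006	
left iliac artery	local	iliac_artery_left	iliac_artery_left
right iliac artery	local	iliac_artery_right	iliac_artery_right
left iliac vein	local	iliac_vena_left	iliac_vena_left
right iliac vein	local	iliac_vena_right	iliac_vena_right
small bowel	local	small_bowel	small_bowel
duodenum	sct	38848004	
colon	sct	71854001	
rib left 1	local	rib_left_1	rib_left_1
rib left 2	local	rib_left_2	rib_left_2
rib left 3	local	rib_left_3	rib_left_3
rib left 4	local	rib_left_4	rib_left_4
rib left 5	local	rib_left_5	rib_left_5
rib left 6	local	rib_left_6	rib_left_6
rib left 7	local	rib_left_7	rib_left_7
rib left 8	local	rib_left_8	rib_left_8
rib left 9	local	rib_left_9	rib_left_9
rib left 10	local	rib_left_10	rib_left_10
rib left 11	local	rib_left_11	rib_left_11
rib left 12	local	rib_left_12	rib_left_12
rib right 1	local	rib_right_1	rib_right_1
rib right 2	local	rib_right_2	rib_right_2
rib right 3	local	rib_right_3	rib_right_3
rib right 4	local	rib_right_4	rib_right_4
rib right 5	local	rib_right_5	rib_right_5
rib right 6	local	rib_right_6	rib_right_6
rib right 7	local	rib_right_7	rib_right_7
rib right 8	local	rib_right_8	rib_right_8
rib right 9	local	rib_right_9	rib_right_9
rib right 10	local	rib_right_10	rib_right_10
rib right 11	local	rib_right_11	rib_right_11
rib right 12	local	rib_right_12	rib_right_12
left humerus	local	humerus_left	humerus_left
right humerus	local	humerus_right	humerus_right
left scapula	local	scapula_left	scapula_left
right scapula	local	scapula_right	scapula_right
left clavicle	local	clavicula_left	clavicula_left
right clavicle	local	clavicula_right	clavicula_right
left femur	local	femur_left	femur_left
right femur	local	femur_right	femur_right
left hip bone	local	hip_left	hip_left
right hip bone	local	hip_right	hip_right
sacrum	local	sacrum	
face	local	face	
left gluteus maximus	local	gluteus_maximus_left	gluteus_maximus_left
right gluteus maximus	local	gluteus_maximus_right	gluteus_maximus_right
left gluteus medius	local	gluteus_medius_left	gluteus_medius_left
right gluteus medius	local	gluteus_medius_right	gluteus_medius_right
left gluteus minimus	local	gluteus_minimus_left	gluteus_minimus_left
right gluteus minimus	local	gluteus_minimus_right	gluteus_minimus_right
left autochthonous back muscle	local	autochthon_left	autochthon_left
right autochthonous back muscle	local	autochthon_right	autochthon_right
left iliopsoas	local	iliopsoas_left	iliopsoas_left
right iliopsoas	local	iliopsoas_right	iliopsoas_right
urinary bladder	sct	89837001	urinary_bladder
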