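participant,gender,age,perceived_performance,bci_experience,condition,perceived_control,frustration,mi_conversion_pct,positive_feedback_pct,fish_caught,fish_lost
1,F,27,0.85,Yes,normal,1.00,0.17,85,85,0,0
3,M,29,0.95,Yes,normal,1.00,0.00,85,85,6,0
4,M,60,0.35,No,normal,0.33,1.00,55,55,3,2
5,M,27,NA,No,normal,0.33,0.50,60,60,5,1
6,M,22,0.7,Yes,normal,0.67,0.50,50,50,4,2
7,F,23,0.75,Yes,normal,1.00,0.17,85,85,8,0
8,M,24,0.2,Yes,normal,0.17,0.67,25,25,1,4
9,M,24,0.75,Yes,normal,0.83,0.33,100,100,8,0
10,F,23,0.8,Yes,normal,0.67,0.67,65,65,4,0
11,F,22,0.075,Yes,normal,0.00,1.00,0,0,0,6
12,F,33,0.6,No,normal,0.67,0.17,70,70,6,0
13,F,24,0.5,No,normal,1.00,0.00,80,80,6,0
14,M,22,0.15,Yes,normal,0.00,0.83,15,15,1,5
15,M,24,0.35,No,normal,0.33,0.67,25,25,2,4
16,M,21,0.6,No,normal,0.50,0.33,35,35,2,3
17,M,28,0.35,No,normal,0.50,0.83,65,65,5,0
18,M,26,0.45,Yes,normal,0.67,0.50,75,75,7,0
19,F,25,0.5,Yes,normal,0.50,0.17,60,60,4,2
1,F,27,0.85,Yes,augmented_success,0.67,0.33,95,65,0,0
3,M,29,0.95,Yes,augmented_success,0.83,0.17,80,60,6,0
4,M,60,0.35,No,augmented_success,0.33,1.00,15,15,1,5
5,M,27,NA,No,augmented_success,0.33,0.17,60,50,4,1
6,M,22,0.7,Yes,augmented_success,0.50,0.67,15,15,1,5
7,F,23,0.75,Yes,augmented_success,0.33,0.50,90,55,5,2
8,M,24,0.2,Yes,augmented_success,0.33,0.67,50,35,1,4
9,M,24,0.75,Yes,augmented_success,0.17,0.83,30,20,0,5
10,F,23,0.8,Yes,augmented_success,0.33,0.33,35,25,2,4
11,F,22,0.075,Yes,augmented_success,0.00,1.00,15,15,1,5
12,F,33,0.6,No,augmented_success,0.17,0.50,85,70,8,0
13,F,24,0.5,No,augmented_success,0.50,0.17,75,50,4,2
14,M,22,0.15,Yes,augmented_success,0.33,0.67,35,30,2,3
15,M,24,0.35,No,augmented_success,0.67,0.33,65,50,6,2
16,M,21,0.6,No,augmented_success,1.00,0.17,45,45,5,3
17,M,28,0.35,No,augmented_success,0.67,0.67,45,45,6,2
18,M,26,0.45,Yes,augmented_success,0.17,0.67,85,60,5,2
19,F,25,0.5,Yes,augmented_success,0.67,0.17,55,45,5,2
1,F,27,0.85,Yes,input_override,0.50,0.50,100,100,0,0
3,M,29,0.95,Yes,input_override,0.50,0.17,95,95,8,0
4,M,60,0.35,No,input_override,0.17,1.00,5,35,2,3
5,M,27,NA,No,input_override,0.50,0.50,55,70,6,0
6,M,22,0.7,Yes,input_override,0.67,0.67,35,50,3,2
7,F,23,0.75,Yes,input_override,0.67,0.50,95,100,7,0
8,M,24,0.2,Yes,input_override,0.33,0.33,30,55,5,2
9,M,24,0.75,Yes,input_override,0.50,0.50,95,95,8,0
10,F,23,0.8,Yes,input_override,0.50,0.17,15,40,2,3
11,F,22,0.075,Yes,input_override,0.00,1.00,5,35,2,4
12,F,33,0.6,No,input_override,0.33,0.67,50,60,4,1
13,F,24,0.5,No,input_override,0.67,0.83,90,95,7,0
14,M,22,0.15,Yes,input_override,0.00,0.50,30,50,3,2
15,M,24,0.35,No,input_override,0.67,0.50,65,75,7,0
16,M,21,0.6,No,input_override,0.83,0.33,40,65,4,1
17,M,28,0.35,No,input_override,0.33,0.83,30,60,4,1
18,M,26,0.45,Yes,input_override,0.33,0.50,65,70,5,0
19,F,25,0.5,Yes,input_override,0.33,0.50,45,60,4,2
1,F,27,0.85,Yes,mitigated_failure,0.50,0.33,90,60,0,0
3,M,29,0.95,Yes,mitigated_failure,0.67,0.17,80,55,4,0
4,M,60,0.35,No,mitigated_failure,0.00,1.00,10,5,0,4
5,M,27,NA,No,mitigated_failure,0.33,0.33,70,50,4,1
6,M,22,0.7,Yes,mitigated_failure,0.67,0.33,30,25,1,2
7,F,23,0.75,Yes,mitigated_failure,0.33,0.50,50,40,2,1
8,M,24,0.2,Yes,mitigated_failure,0.33,0.33,25,25,1,3
9,M,24,0.75,Yes,mitigated_failure,0.67,0.67,75,55,5,0
10,F,23,0.8,Yes,mitigated_failure,0.33,0.50,30,30,1,2
11,F,22,0.075,Yes,mitigated_failure,0.17,1.00,25,20,1,3
12,F,33,0.6,No,mitigated_failure,0.00,0.83,80,65,5,0
13,F,24,0.5,No,mitigated_failure,0.67,0.00,75,55,4,0
14,M,22,0.15,Yes,mitigated_failure,,,,,,
15,M,24,0.35,No,mitigated_failure,0.50,0.50,55,50,3,1
16,M,21,0.6,No,mitigated_failure,0.67,0.33,15,15,1,3
17,M,28,0.35,No,mitigated_failure,0.17,1.00,40,25,1,2
18,M,26,0.45,Yes,mitigated_failure,0.33,0.50,85,55,4,0
19,F,25,0.5,Yes,mitigated_failure,0.67,0.00,60,45,3,1
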