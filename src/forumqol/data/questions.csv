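qid,text,instrument,n_levels,fine_group,coarse_group
1,"Do you have any trouble doing strenuous activities, like carrying a heavy shopping bag or a suitcase?",C30,4,Physical functioning,FUNCTIONAL
2,"Do you have any trouble taking a long walk?",C30,4,Physical functioning,FUNCTIONAL
3,"Do you have any trouble taking a short walk outside of the house?",C30,4,Physical functioning,FUNCTIONAL
4,"Do you need to stay in bed or a chair during the day?",C30,4,Physical functioning,FUNCTIONAL
5,"Do you need help with eating, dressing, washing yourself or using the toilet?",C30,4,Physical functioning,FUNCTIONAL
6,"Were you limited in doing either your work or other daily activities?",C30,4,Role functioning,FUNCTIONAL
7,"Were you limited in pursuing your hobbies or other leisure time activities?",C30,4,Role functioning,FUNCTIONAL
8,"Were you short of breath?",C30,4,Dyspnea,SYMPTOMATIC
9,"Have you had pain?",C30,4,Pain,SYMPTOMATIC
10,"Did you need to rest?",C30,4,Fatigue,SYMPTOMATIC
11,"Have you had trouble sleeping?",C30,4,Insomnia,SYMPTOMATIC
12,"Have you felt weak?",C30,4,Fatigue,SYMPTOMATIC
13,"Have you lacked appetite?",C30,4,Appetite loss,SYMPTOMATIC
14,"Have you felt nauseated?",C30,4,Nausea and vomiting,SYMPTOMATIC
15,"Have you vomited?",C30,4,Nausea and vomiting,SYMPTOMATIC
16,"Have you been constipated?",C30,4,Constipation,SYMPTOMATIC
17,"Have you had diarrhea?",C30,4,Diarrhea,SYMPTOMATIC
18,"Were you tired?",C30,4,Fatigue,SYMPTOMATIC
19,"Did pain interfere with your daily activities?",C30,4,Pain,SYMPTOMATIC
20,"Have you had difficulty in concentrating on things, like reading a newspaper or watching television?",C30,4,Cognitive functioning,FUNCTIONAL
21,"Did you feel tense?",C30,4,Emotional functioning,FUNCTIONAL
22,"Did you worry?",C30,4,Emotional functioning,FUNCTIONAL
23,"Did you feel irritable?",C30,4,Emotional functioning,FUNCTIONAL
24,"Did you feel depressed?",C30,4,Emotional functioning,FUNCTIONAL
25,"Have you had difficulty remembering things?",C30,4,Cognitive functioning,FUNCTIONAL
26,"Has your physical condition or medical treatment interfered with your family life?",C30,4,Social functioning,FUNCTIONAL
27,"Has your physical condition or medical treatment interfered with your social activities?",C30,4,Social functioning,FUNCTIONAL
28,"Has your physical condition or medical treatment caused you financial difficulties?",C30,4,Financial difficulties,SYMPTOMATIC
29,"How would you rate your overall health during the past week?",C30,7,Global health,GLOBAL
30,"How would you rate your overall quality of life during the past week?",C30,7,Global health,GLOBAL
31,"Did you have a dry mouth?",BR23,4,Systemic therapy side effects,SYMPTOMATIC
32,"Did food and drink taste different than usual?",BR23,4,Systemic therapy side effects,SYMPTOMATIC
33,"Were your eyes painful, irritated or watery?",BR23,4,Systemic therapy side effects,SYMPTOMATIC
34,"Have you lost any hair?",BR23,4,Systemic therapy side effects,SYMPTOMATIC
35,"Were you upset by the loss of your hair?",BR23,4,Upset by hair loss,SYMPTOMATIC
36,"Did you feel ill or unwell?",BR23,4,Systemic therapy side effects,SYMPTOMATIC
37,"Did you have hot flushes?",BR23,4,Systemic therapy side effects,SYMPTOMATIC
38,"Did you have headaches?",BR23,4,Systemic therapy side effects,SYMPTOMATIC
39,"Have you felt physically less attractive as a result of your disease or treatment?",BR23,4,Body image,FUNCTIONAL
40,"Have you been feeling less feminine as a result of your disease or treatment?",BR23,4,Body image,FUNCTIONAL
41,"Did you find it difficult to look at yourself naked?",BR23,4,Body image,FUNCTIONAL
42,"Have you been dissatisfied with your body?",BR23,4,Body image,FUNCTIONAL
43,"Were you worried about your health in the future?",BR23,4,Future perspective,FUNCTIONAL
44,"To what extent were you interested in sex?",BR23,4,Sexual functioning,FUNCTIONAL
45,"To what extent were you sexually active? (with or without intercourse)",BR23,4,Sexual functioning,FUNCTIONAL
46,"To what extent was sex enjoyable for you?",BR23,4,Sexual enjoyment,FUNCTIONAL
47,"Did you have any pain in your arm or shoulder?",BR23,4,Arm symptoms,SYMPTOMATIC
48,"Did you have a swollen arm or hand?",BR23,4,Arm symptoms,SYMPTOMATIC
49,"Was it difficult to raise your arm or to move it sideways?",BR23,4,Arm symptoms,SYMPTOMATIC
50,"Have you had any pain in the area of your affected breast?",BR23,4,Breast symptoms,SYMPTOMATIC
51,"Was the area of your affected breast swollen?",BR23,4,Breast symptoms,SYMPTOMATIC
52,"Was the area of your affected breast oversensitive?",BR23,4,Breast symptoms,SYMPTOMATIC
53,"Have you had skin problems on or in the area of your affected breast (e.g., itchy, dry, flaky)?",BR23,4,Breast symptoms,SYMPTOMATIC
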