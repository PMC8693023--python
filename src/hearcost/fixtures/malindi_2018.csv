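name,category,bucket,model1,model2,model3
Audiometry Software,capital,equipment,3000,0,3000
Headphones/Cell Phones,capital,equipment,1300,1011,1300
Video Otoscope,capital,equipment,460,460,460
Disposable Speculums,recurrent,medical_supplies,20,20,20
Ear Curette,recurrent,medical_supplies,7,7,7
Ear Alligator,recurrent,medical_supplies,12,12,12
Alcohol Wipes,recurrent,medical_supplies,3,3,3
Straight Pick,recurrent,medical_supplies,47,47,47
Clotrimazole Powder,recurrent,medical_supplies,5,5,5
Cipro/Dexa Eye Drops,recurrent,medical_supplies,48,48,48
Augmentin Tablets,recurrent,medical_supplies,40,40,40
Resident Salary,recurrent,staff,905,0,0
Teacher Salary,recurrent,staff,15,0,15
CHW,recurrent,staff,60,60,60
Nurse/Clinical Officer,recurrent,staff,120,120,120
Ground Transportation,recurrent,transport,300,300,300
Equipment Maintenance,recurrent,maintenance,1346,746,1346
Flight,recurrent,resident_travel,1300,300,0
Visa,recurrent,resident_travel,50,50,0
Vaccine/Malaria Prophylaxis,recurrent,resident_travel,430,388,0
Housing,recurrent,resident_travel,325,325,0
Food,recurrent,resident_travel,46,46,0
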